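"""Delimited-text readers/writers, run configuration and the full pipeline.

All tables are UTF-8 CSV with a header row.  Column schemas:

fish table
    fish_id, provenance (wild|captive), sex (F|M|unknown), return_year,
    sea_age (grilse|MSW) [, fork_length, trap_direction,
    spawning_cohorts (';'-joined years), cohort_weights (';'-joined floats)]
parentage table
    offspring_id, parent_id [, n_parents_assigned]
census table
    year, provenance, sea_age, count [, mean_length]
productivity series
    year, spawners, recruits, productivity, log_productivity, prop_captive,
    residual

Every pipeline output is reproducible from the manifest's recorded seed and
configuration; no timestamps are written, so repeated runs with the same
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import pedigree, productivity, rrs
from .errors import SalarfitError, SchemaError, ValidationError
from .pedigree import ParentageTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _split_list(s, cast):
    if pd.isna(s) or s == "":
        return None
    return [cast(v) for v in str(s).split(";")]


def read_fish_table(path) -> pd.DataFrame:
    fish = pd.read_csv(path)
    pedigree.validate_fish(fish)
    if "spawning_cohorts" in fish.columns:
        fish["spawning_cohorts"] = [
            _split_list(s, lambda v: int(float(v))) for s in fish["spawning_cohorts"]
        ]
    if "cohort_weights" in fish.columns:
        fish["cohort_weights"] = [_split_list(s, float) for s in fish["cohort_weights"]]
    logger.info("read %d fish records from %s", len(fish), path)
    return fish


def write_fish_table(fish: pd.DataFrame, path) -> None:
    out = fish.copy()
    for col in ("spawning_cohorts", "cohort_weights"):
        if col in out.columns:
            out[col] = [
                ";".join(str(v) for v in row) if row is not None else ""
                for row in out[col]
            ]
    out.to_csv(path, index=False)


def read_parentage_table(
    path, epsilon: float = 0.0, n_offspring_sampled: int | None = None
) -> ParentageTable:
    links = pd.read_csv(path)
    return ParentageTable(links, epsilon=epsilon, n_offspring_sampled=n_offspring_sampled)


def write_parentage_table(parentage: ParentageTable | pd.DataFrame, path) -> None:
    links = parentage.links if isinstance(parentage, ParentageTable) else parentage
    links.to_csv(path, index=False)


def read_census_table(path) -> pd.DataFrame:
    census = pd.read_csv(path)
    productivity.validate_census(census)
    return census


def read_series_table(path) -> pd.DataFrame:
    series = pd.read_csv(path)
    missing = [c for c in productivity.SERIES_COLUMNS if c not in series.columns]
    if missing:
        raise SchemaError(f"productivity series missing column(s): {missing}")
    return series


def read_tables(
    fish_path, parentage_path, census_path=None, epsilon: float = 0.0
) -> tuple[pd.DataFrame, ParentageTable, pd.DataFrame | None]:
    """Read and validate the three pipeline inputs."""
    fish = read_fish_table(fish_path)
    parentage = read_parentage_table(parentage_path, epsilon=epsilon)
    census = read_census_table(census_path) if census_path is not None else None
    return fish, parentage, census


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return json.loads(obj.to_json())
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration (CLI flags mirror these fields)."""

    fish_path: str | None = None
    parentage_path: str | None = None
    census_path: str | None = None
    series_path: str | None = None  #: precomputed productivity series (optional)
    output_dir: str = "salarfit_out"
    cohorts: Sequence[int] | None = None  #: focal spawning cohorts (None: infer)
    epsilon: float = 0.0
    n_perm: int = 1_000_000
    tie_rule: str = "weak"
    weight_scheme: str = "total"  #: 'total', 'captive' or 'custom'
    custom_weights: Sequence[float] | None = None
    knots: int = 9
    lags: tuple[int, int] = (4, 5)
    seed: int = 0
    overrides: dict = field(default_factory=dict)  #: fish_id -> cohorts/weights
    mean_intrusion: float | None = None  #: x for percent_reduction (None: series mean)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.lags is not None:
            cfg.lags = tuple(int(v) for v in cfg.lags)
        return cfg


def infer_cohorts(fish: pd.DataFrame) -> list[int]:
    """Spawning-cohort years in which both provenances are present."""
    member = rrs._cohort_membership(fish)
    years: dict[int, set] = {}
    for fid, cohorts in member.items():
        for t in cohorts:
            years.setdefault(t, set())
    prov = fish.set_index("fish_id")["provenance"]
    for fid, cohorts in member.items():
        for t in cohorts:
            years[t].add(prov[fid])
    return sorted(t for t, provs in years.items() if provs == {"wild", "captive"})


class PipelineError(SalarfitError, RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``output_dir``.

    Outputs: ``lrs.csv``, ``rrs_report.csv`` (cohort x RRS x p table),
    ``productivity_series.csv``, ``summary.json`` (overall RRS, combined
    test, zero-LRS analyses, intrusion regression) and ``manifest.json``.
    Partial outputs are removed if any stage fails.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    def _write_json(obj, name: str) -> None:
        p = outdir / name
        write_json(obj, p)
        written.append(p)

    stage = "read"
    summary: dict = {}
    try:
        fish, parentage, census = read_tables(
            config.fish_path, config.parentage_path, config.census_path,
            epsilon=config.epsilon,
        )

        stage = "cohorts"
        fish = pedigree.assign_spawning_cohorts(fish, overrides=config.overrides)
        cohorts = (
            [int(c) for c in config.cohorts]
            if config.cohorts is not None
            else infer_cohorts(fish)
        )

        stage = "lrs"
        lrs = pedigree.compute_lrs(parentage, fish)
        _write_csv(lrs, "lrs.csv")

        stage = "rrs"
        table = rrs.cohort_fitness_table(
            fish, lrs, parentage, cohorts,
            epsilon=config.epsilon, n_perm=config.n_perm,
            tie_rule=config.tie_rule, seed=config.seed, lags=config.lags,
        )
        _write_csv(table, "rrs_report.csv")
        if config.weight_scheme == "total":
            weights = (table["n_captive"] + table["n_wild"]).to_numpy(float)
        elif config.weight_scheme == "captive":
            weights = table["n_captive"].to_numpy(float)
        elif config.weight_scheme == "custom":
            if config.custom_weights is None:
                raise ValidationError("weight_scheme 'custom' requires custom_weights")
            weights = np.asarray(config.custom_weights, float)
        else:
            raise ValidationError(f"unknown weight_scheme {config.weight_scheme!r}")
        combined = rrs.fisher_combined(
            table["perm_p"].tolist(), n_perm=config.n_perm
        )
        summary["overall_rrs"] = rrs.overall_rrs(table["rrs"].tolist(), weights)
        summary["weights"] = {"scheme": config.weight_scheme, "values": weights}
        summary["fisher_combined"] = combined
        summary["mixed_population_reduction_pct"] = rrs.mixed_population_reduction(
            table["n_captive"].tolist(), table["rrs"].tolist(), table["n_wild"].tolist()
        )

        stage = "zero_lrs"
        member = rrs._cohort_membership(fish)
        focal = fish[[bool(set(member.get(f, ())) & set(cohorts)) for f in fish["fish_id"]]]
        lrs_map = lrs.set_index("fish_id")["lrs"]
        vals = {
            g: lrs_map.loc[focal.loc[focal["provenance"] == g, "fish_id"]].to_numpy()
            for g in ("captive", "wild")
        }
        chi2, p_zero = rrs.zero_lrs_proportion_test(
            int((vals["captive"] == 0).sum()), len(vals["captive"]),
            int((vals["wild"] == 0).sum()), len(vals["wild"]),
        )
        summary["zero_lrs_proportion_test"] = {"chi2": chi2, "one_sided_p": p_zero}
        zrrs, zp = rrs.zero_excluded_rrs(
            vals["captive"], vals["wild"], n_perm=config.n_perm,
            seed=np.random.default_rng(config.seed + 1),
        )
        summary["zero_excluded"] = {"rrs": zrrs, "perm_p": zp}

        stage = "productivity"
        if config.series_path is not None:
            series = read_series_table(config.series_path)
        elif census is not None:
            series = productivity.recruits_per_spawner(census, lags=config.lags)
        else:
            series = None
        if series is not None and len(series) >= config.knots + 2:
            gam = productivity.fit_density_gam(series, k=config.knots)
            series = productivity.attach_residuals(series, gam)
            sub = series.dropna(subset=["residual"])
            reg = productivity.intrusion_regression(
                sub["residual"], sub["prop_captive"]
            )
            corr = productivity.density_intrusion_correlation(
                sub["spawners"], sub["prop_captive"]
            )
            x = (
                config.mean_intrusion
                if config.mean_intrusion is not None
                else float(sub["prop_captive"].mean())
            )
            summary["productivity"] = {
                "gam": {"k": gam.k, "alpha": gam.alpha, "edf": gam.edf,
                        "criterion": gam.criterion, "basis": gam.basis},
                "intrusion_regression": reg,
                "density_intrusion_correlation": {
                    "r": corr.r, "t": corr.t_stat, "df": corr.df, "p": corr.p},
                "mean_intrusion": x,
                "percent_reduction_at_mean_intrusion":
                    productivity.percent_reduction(reg.slope, x),
            }
            _write_csv(series, "productivity_series.csv")
        elif series is not None:
            logger.warning(
                "productivity series too short for a %d-knot fit; skipping GAM",
                config.knots,
            )
            _write_csv(series, "productivity_series.csv")

        stage = "report"
        _write_json(summary, "summary.json")
        from . import __version__

        # the manifest lives inside output_dir; recording the path would only
        # break byte-identity of repeated runs
        cfg_record = {
            k: v for k, v in dataclasses.asdict(config).items() if k != "output_dir"
        }
        manifest = {
            "package": "salarfit",
            "version": __version__,
            "config": cfg_record,
            "cohorts": cohorts,
            "n_cohorts": len(cohorts),
            "substitutions": combined.substitutions,
        }
        _write_json(manifest, "manifest.json")
    except Exception as exc:  # noqa: BLE001 - propagate with stage, clean partials
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return {"summary": summary, "rrs_table": table, "series": series,
            "manifest": manifest, "output_dir": str(outdir)}
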