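"""Synthetic pedigree, census and productivity data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, for a sea-ranched salmon system with a total trapping census:

* two provenances (wild-bred and captive-bred potential spawners) with a true
  fitness ratio ``true_rrs`` (captive mean offspring = rho x wild mean);
* zero-inflated offspring counts — a hurdle model with provenance-specific
  zero probabilities and a shifted negative-binomial positive part;
* every offspring has two true parents (an opposite-sex co-parent drawn with
  probability proportional to its own brood size, which preserves the
  provenance fitness ratio and keeps never-spawners at LRS zero);
* incomplete sampling of parents (``parent_sampling_frac``) and offspring
  (``offspring_sampling_frac``), so single-parent assignments emerge the way
  they do in a real pedigree;
* parentage assignment error: each recorded link is corrupted with
  probability epsilon and reassigned to a random other sampled parent;
* a ~90/10 grilse/MSW sea-age split and a configurable sex ratio;
* a density-dependent productivity series with a multiplicative (log-scale)
  hatchery-intrusion effect.

Ground truth needed for parameter-recovery tests is returned alongside the
data as :class:`SimulationTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pedigree import ParentageTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "DensityParams",
    "simulate_pedigree",
    "simulate_productivity_series",
]


@dataclass
class SimulationConfig:
    """Generating parameters for the synthetic pedigree.

    Defaults describe the study conditions the analysis targets: six focal
    spawning cohorts, ~19% captive-bred spawners, a true captive/wild fitness
    ratio of 0.36, hurdle zero-probabilities chosen so the positive-part
    (zero-excluded) fitness ratio is 0.81, a 90/10 grilse/MSW split and a
    1.4x captive fecundity multiplier.
    """

    n_cohorts: int = 6
    n_wild: int = 350  #: wild-bred potential spawners per cohort
    n_captive: int = 82  #: captive-bred potential spawners per cohort
    true_rrs: float = 0.36  #: rho, captive/wild ratio of mean offspring counts
    zero_prob_wild: float = 0.55  #: pi_w, P(LRS = 0) for wild-bred fish
    zero_prob_captive: float = 0.80  #: pi_c
    mean_positive_wild: float = 2.2  #: mu, mean offspring count of successful wild fish
    dispersion: float = 0.7  #: theta, negative-binomial dispersion of the positive part
    parent_sampling_frac: float = 0.5  #: f_p
    offspring_sampling_frac: float = 0.8  #: f_o
    assignment_error: float = 0.02  #: epsilon
    grilse_frac: float = 0.9
    sex_ratio: float = 0.5  #: probability female
    fecundity_multiplier_captive: float = 1.4
    misassignment_scope: str = "any"  #: 'any' (provenance-blind) or 'within'
    second_generation: bool = True  #: draw grand-offspring for sampled offspring
    cohort_years: tuple | None = None  #: default: 6 years spaced 7 apart from 1977
    first_cohort_year: int = 1977
    cohort_spacing: int = 7  # > recruit lags, so generations never alias
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "n_wild", "n_captive"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")
        if self.n_cohorts < 1:
            raise ValidationError("n_cohorts must be >= 1")
        for name in (
            "zero_prob_wild",
            "zero_prob_captive",
            "grilse_frac",
            "sex_ratio",
        ):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("parent_sampling_frac", "offspring_sampling_frac"):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and 0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not (np.isfinite(self.assignment_error) and 0.0 <= self.assignment_error < 1.0):
            raise ValidationError("assignment_error must be in [0, 1)")
        for name in ("true_rrs", "dispersion", "fecundity_multiplier_captive"):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive, got {v}")
        if not (np.isfinite(self.mean_positive_wild) and self.mean_positive_wild >= 1):
            raise ValidationError("mean_positive_wild must be >= 1 (hurdle positive part)")
        if self.misassignment_scope not in ("any", "within"):
            raise ValidationError("misassignment_scope must be 'any' or 'within'")
        if self.zero_prob_captive < 1.0 and self.mean_positive_captive < 1.0 - 1e-12:
            raise ValidationError(
                "implied captive positive-part mean "
                f"{self.mean_positive_captive:.3g} < 1; raise true_rrs, "
                "mean_positive_wild or zero_prob_captive"
            )
        if self.cohort_years is not None:
            self.cohort_years = tuple(int(y) for y in self.cohort_years)
            if len(self.cohort_years) != self.n_cohorts:
                raise ValidationError("cohort_years length must equal n_cohorts")

    @property
    def years(self) -> tuple:
        if self.cohort_years is not None:
            return self.cohort_years
        return tuple(
            self.first_cohort_year + self.cohort_spacing * i
            for i in range(self.n_cohorts)
        )

    @property
    def mean_overall_wild(self) -> float:
        """Generating per-capita mean offspring count, wild-bred."""
        return (1.0 - self.zero_prob_wild) * self.mean_positive_wild

    @property
    def mean_overall_captive(self) -> float:
        return self.true_rrs * self.mean_overall_wild

    @property
    def mean_positive_captive(self) -> float:
        """Positive-part mean implied by rho and the zero probabilities."""
        if self.zero_prob_captive >= 1.0:
            return 0.0
        return self.mean_overall_captive / (1.0 - self.zero_prob_captive)


@dataclass
class SimulationTruth:
    """Generating parameters and realized tallies for recovery tests."""

    config: SimulationConfig | None
    expected_mean_lrs: dict = field(default_factory=dict)  #: provenance -> generating mean
    per_cohort: pd.DataFrame | None = None  #: realized true means and tallies
    beta_true: float | None = None  #: productivity intrusion slope (series runs)
    extra: dict = field(default_factory=dict)


class PedigreeBundle(NamedTuple):
    parentage: ParentageTable
    fish: pd.DataFrame
    census: pd.DataFrame
    truth: SimulationTruth


def _hurdle_counts(
    rng: np.random.Generator, n: int, zero_prob: float, pos_mean: float, theta: float
) -> np.ndarray:
    """Zero-inflated counts: 0 w.p. zero_prob, else 1 + NB(pos_mean - 1, theta)."""
    counts = np.zeros(n, dtype=np.int64)
    if n == 0 or zero_prob >= 1.0:
        return counts
    pos = rng.random(n) < (1.0 - zero_prob)
    n_pos = int(pos.sum())
    extra_mean = pos_mean - 1.0
    if n_pos and extra_mean > 0:
        lam = rng.gamma(theta, extra_mean / theta, size=n_pos)
        counts[pos] = 1 + rng.poisson(lam)
    else:
        counts[pos] = 1
    return counts


def _fork_lengths(rng: np.random.Generator, sea_age: np.ndarray) -> np.ndarray:
    L = np.where(
        sea_age == "grilse",
        rng.normal(62.0, 4.0, size=sea_age.size),
        rng.normal(78.0, 5.0, size=sea_age.size),
    )
    return np.clip(L, 40.0, None).round(1)


def _choose_coparents(
    rng: np.random.Generator,
    focal_sex: np.ndarray,
    parent_sex: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Opposite-sex co-parent index for each offspring, weighted by brood size.

    Returns -1 where no eligible co-parent exists (empty or zero-weight pool).
    """
    co = np.full(focal_sex.size, -1, dtype=np.int64)
    for sex, other in (("F", "M"), ("M", "F")):
        mask = focal_sex == sex
        if not mask.any():
            continue
        pool = np.flatnonzero(parent_sex == other)
        w = weights[pool].astype(float)
        if pool.size == 0 or w.sum() <= 0:
            continue
        co[mask] = rng.choice(pool, size=int(mask.sum()), p=w / w.sum())
    return co


def _corrupt_links(
    rng: np.random.Generator,
    true_parent_idx: np.ndarray,
    candidate_pools: dict,
    pool_keys: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """Reassign each link w.p. epsilon to a uniform random *other* candidate."""
    out = true_parent_idx.copy()
    if epsilon <= 0 or out.size == 0:
        return out
    hit = np.flatnonzero(rng.random(out.size) < epsilon)
    for i in hit:
        pool = candidate_pools[pool_keys[i]]
        if pool.size < 2:
            continue  # no *other* parent to misassign to
        j = int(pool[rng.integers(pool.size)])
        while j == out[i]:
            j = int(pool[rng.integers(pool.size)])
        out[i] = j
    return out


def simulate_pedigree(config: SimulationConfig) -> PedigreeBundle:
    """Generate a two-generation pedigree with census and ground truth.

    Per focal cohort: potential spawners of both provenances draw hurdle
    offspring counts; each offspring receives an opposite-sex co-parent
    weighted by brood size; parents and offspring are thinned by the sampling
    fractions; links of sampled offspring to sampled parents are recorded and
    corrupted with probability epsilon.  Sampled offspring then draw their
    own (wild-parameter) second-generation broods so that mating-pair
    grand-offspring comparisons are possible.  Deterministic given the seed.
    """
    root = np.random.default_rng(config.seed)
    rngs = root.spawn(6)
    r_par, r_cnt, r_pair, r_samp, r_assign, r_gen2 = rngs

    fish_frames: list[pd.DataFrame] = []
    census_frames: list[pd.DataFrame] = []
    link_off: list[np.ndarray] = []
    link_par: list[np.ndarray] = []
    truth_rows: list[dict] = []

    for t in config.years:
        n_w, n_c = config.n_wild, config.n_captive
        n = n_w + n_c
        prov = np.array(["wild"] * n_w + ["captive"] * n_c)
        ids = np.array([f"P{t}_{i:06d}" for i in range(n)])
        sex = np.where(r_par.random(n) < config.sex_ratio, "F", "M")
        sea_age = np.where(r_par.random(n) < config.grilse_frac, "grilse", "MSW")
        length = _fork_lengths(r_par, sea_age)
        # trap direction mirrors the sampling asymmetry of a ranched system:
        # wild fish mostly sampled as kelts downstream, captive-bred upstream
        trap = np.where(
            prov == "wild",
            np.where(r_par.random(n) < 0.9421, "downstream", "upstream"),
            np.where(r_par.random(n) < 0.9474, "upstream", "downstream"),
        )

        counts = np.empty(n, dtype=np.int64)
        counts[:n_w] = _hurdle_counts(
            r_cnt, n_w, config.zero_prob_wild, config.mean_positive_wild, config.dispersion
        )
        counts[n_w:] = _hurdle_counts(
            r_cnt, n_c, config.zero_prob_captive, config.mean_positive_captive,
            config.dispersion,
        )

        focal = np.repeat(np.arange(n), counts)
        n_off = focal.size
        co = _choose_coparents(r_pair, sex[focal], sex, counts.astype(float))
        true_lrs = np.bincount(focal, minlength=n)
        true_lrs += np.bincount(co[co >= 0], minlength=n)

        off_ids = np.array([f"O{t}_{j:06d}" for j in range(n_off)])
        off_sex = np.where(r_pair.random(n_off) < config.sex_ratio, "F", "M")
        off_grilse = r_pair.random(n_off) < config.grilse_frac
        off_sea_age = np.where(off_grilse, "grilse", "MSW")
        off_year = np.where(off_grilse, t + 4, t + 5)
        off_length = _fork_lengths(r_pair, off_sea_age)

        parent_sampled = r_samp.random(n) < config.parent_sampling_frac
        off_sampled = r_samp.random(n_off) < config.offspring_sampling_frac

        # recorded links: sampled offspring -> sampled true parents, corrupted
        sampled_idx = np.flatnonzero(parent_sampled)
        pools = {"any": sampled_idx}
        for g in ("wild", "captive"):
            pools[g] = sampled_idx[prov[sampled_idx] == g]
        pairs_off: list[np.ndarray] = []
        pairs_par: list[np.ndarray] = []
        for parent_of in (focal, co):
            ok = off_sampled & (parent_of >= 0) & parent_sampled[np.clip(parent_of, 0, None)]
            tp = parent_of[ok]
            keys = (
                np.full(tp.size, "any")
                if config.misassignment_scope == "any"
                else prov[tp]
            )
            assigned = _corrupt_links(r_assign, tp, pools, keys, config.assignment_error)
            pairs_off.append(off_ids[ok])
            pairs_par.append(ids[assigned])
        link_off.append(np.concatenate(pairs_off))
        link_par.append(np.concatenate(pairs_par))

        # second generation: sampled (wild-bred) offspring reproduce
        gen2_frames = None
        if config.second_generation:
            s_off = np.flatnonzero(off_sampled)
            cnt2 = _hurdle_counts(
                r_gen2, s_off.size, config.zero_prob_wild, config.mean_positive_wild,
                config.dispersion,
            )
            focal2 = np.repeat(s_off, cnt2)  # index into offspring arrays
            n_g = focal2.size
            g_sampled = r_gen2.random(n_g) < config.offspring_sampling_frac
            g_ids = np.array([f"G{t}_{j:06d}" for j in range(n_g)])
            g_grilse = r_gen2.random(n_g) < config.grilse_frac
            g_sea_age = np.where(g_grilse, "grilse", "MSW")
            g_year = off_year[focal2] + np.where(g_grilse, 4, 5)
            g_sex = np.where(r_gen2.random(n_g) < config.sex_ratio, "F", "M")
            g_length = _fork_lengths(r_gen2, g_sea_age)
            ok = g_sampled
            tp = focal2[ok]
            pool2 = {"any": s_off, "wild": s_off, "captive": np.array([], dtype=np.int64)}
            assigned2 = _corrupt_links(
                r_gen2, tp, pool2, np.full(tp.size, "any"), config.assignment_error
            )
            link_off.append(g_ids[ok])
            link_par.append(off_ids[assigned2])
            gen2_frames = dict(
                ids=g_ids, sex=g_sex, sea_age=g_sea_age, year=g_year,
                length=g_length, sampled=g_sampled,
            )

        # sampled fish enter the fish table; everyone enters the census
        def _frame(ids_, prov_, sex_, year_, age_, len_, trap_=None):
            return pd.DataFrame(
                {
                    "fish_id": ids_,
                    "provenance": prov_,
                    "sex": sex_,
                    "return_year": np.asarray(year_, dtype=int),
                    "sea_age": age_,
                    "fork_length": len_,
                    "trap_direction": trap_ if trap_ is not None else "",
                }
            )

        fish_frames.append(
            _frame(
                ids[parent_sampled], prov[parent_sampled], sex[parent_sampled],
                np.full(int(parent_sampled.sum()), t), sea_age[parent_sampled],
                length[parent_sampled], trap[parent_sampled],
            )
        )
        fish_frames.append(
            _frame(
                off_ids[off_sampled], "wild", off_sex[off_sampled],
                off_year[off_sampled], off_sea_age[off_sampled],
                off_length[off_sampled],
                np.where(r_samp.random(int(off_sampled.sum())) < 0.9421,
                         "downstream", "upstream"),
            )
        )
        census_frames.append(
            _frame(ids, prov, sex, np.full(n, t), sea_age, length)
        )
        census_frames.append(
            _frame(off_ids, "wild", off_sex, off_year, off_sea_age, off_length)
        )
        if gen2_frames is not None:
            g = gen2_frames
            fish_frames.append(
                _frame(
                    g["ids"][g["sampled"]], "wild", g["sex"][g["sampled"]],
                    g["year"][g["sampled"]], g["sea_age"][g["sampled"]],
                    g["length"][g["sampled"]],
                )
            )
            census_frames.append(
                _frame(g["ids"], "wild", g["sex"], g["year"], g["sea_age"], g["length"])
            )

        for g, sl in (("wild", slice(0, n_w)), ("captive", slice(n_w, n))):
            truth_rows.append(
                {
                    "cohort": t,
                    "provenance": g,
                    "n_parents": int(sl.stop - sl.start),
                    "n_parents_sampled": int(parent_sampled[sl].sum()),
                    "true_mean_lrs": float(true_lrs[sl].mean()) if sl.stop > sl.start else np.nan,
                    "true_mean_own_brood": float(counts[sl].mean()) if sl.stop > sl.start else np.nan,
                    "n_offspring_true": int(n_off),
                    "n_offspring_sampled": int(off_sampled.sum()),
                }
            )

    links = pd.DataFrame(
        {
            "offspring_id": np.concatenate(link_off) if link_off else [],
            "parent_id": np.concatenate(link_par) if link_par else [],
        }
    ).drop_duplicates(ignore_index=True)
    per_off = links.groupby("offspring_id")["parent_id"].transform("size")
    links["n_parents_assigned"] = per_off.astype(int) if len(links) else per_off

    fish = pd.concat(fish_frames, ignore_index=True)
    census_fish = pd.concat(census_frames, ignore_index=True)
    census = (
        census_fish.groupby(["return_year", "provenance", "sea_age"])
        .agg(count=("fish_id", "size"), mean_length=("fork_length", "mean"))
        .reset_index()
        .rename(columns={"return_year": "year"})
    )

    per_cohort = pd.DataFrame(truth_rows)
    truth = SimulationTruth(
        config=config,
        expected_mean_lrs={
            "wild": config.mean_overall_wild,
            "captive": config.mean_overall_captive,
        },
        per_cohort=per_cohort,
        extra={
            "n_links": int(len(links)),
            "n_offspring_sampled_total": int(
                per_cohort[per_cohort["provenance"] == "wild"]["n_offspring_sampled"].sum()
            ),
        },
    )
    parentage = ParentageTable(
        links,
        epsilon=config.assignment_error,
        n_offspring_sampled=truth.extra["n_offspring_sampled_total"],
    )
    return PedigreeBundle(parentage, fish, census, truth)


# ---------------------------------------------------------------------------
# productivity series
# ---------------------------------------------------------------------------

@dataclass
class DensityParams:
    """Beverton-Holt-shaped density dependence of recruits per spawner.

    log P = log(max_rps) - log(1 + S / half_saturation): productivity is
    ``max_rps`` at vanishing density and halves at ``half_saturation``
    spawners.
    """

    max_rps: float = 2.0
    half_saturation: float = 500.0

    def log_rps(self, spawners) -> np.ndarray:
        return np.log(self.max_rps) - np.log1p(np.asarray(spawners, float) / self.half_saturation)


class SeriesBundle(NamedTuple):
    series: pd.DataFrame
    truth: SimulationTruth


def simulate_productivity_series(
    n_years: int,
    density_params: DensityParams | None = None,
    beta_true: float = -0.686,
    noise_sd: float = 0.25,
    intrusion_range: tuple[float, float] = (0.01, 0.59),
    seed: int | None = 0,
    mean_spawners: float = 700.0,
    spawner_log_sd: float = 0.5,
    spawner_autocorr: float = 0.6,
    first_year: int = 1970,
    max_resample: int = 1000,
) -> SeriesBundle:
    """Stock-recruitment productivity series with a hatchery-intrusion effect.

    Spawner numbers follow a stationary positive process (lognormal AR(1)
    with mean ``mean_spawners``, log-scale sd ``spawner_log_sd`` and lag-1
    autocorrelation ``spawner_autocorr``).  Intrusion proportions p_t are
    independent uniform draws from ``intrusion_range`` — independent of
    density, matching the weak density-intrusion correlation the residual
    method assumes.  Log productivity of cohort t is the Beverton-Holt curve
    at spawner density plus ``beta_true * p_t`` plus Gaussian noise, and
    recruits are R_t = S_t * P_t.
    """
    if n_years < 10:
        raise ValidationError(f"n_years must be >= 10, got {n_years}")
    if noise_sd < 0 or not np.isfinite(noise_sd):
        raise ValidationError("noise_sd must be a non-negative real")
    lo, hi = float(intrusion_range[0]), float(intrusion_range[1])
    if not (0.0 <= lo <= hi < 1.0):
        raise ValidationError("intrusion_range must satisfy 0 <= lo <= hi < 1")
    dp = density_params or DensityParams()
    if dp.max_rps <= 0 or dp.half_saturation <= 0:
        raise ValidationError("density parameters must be positive")
    if mean_spawners <= 0 or spawner_log_sd < 0 or not -1 < spawner_autocorr < 1:
        raise ValidationError("invalid spawner-process parameters")
    rng = np.random.default_rng(seed)

    m = np.log(mean_spawners)
    innov_sd = spawner_log_sd * np.sqrt(1.0 - spawner_autocorr**2)
    x = np.empty(n_years)
    x[0] = m + rng.normal(0.0, spawner_log_sd)
    for y in range(1, n_years):
        x[y] = m + spawner_autocorr * (x[y - 1] - m) + rng.normal(0.0, innov_sd)
    S = np.exp(x)
    n_resampled = 0
    while np.any(S < 1.0):
        bad = S < 1.0
        n_resampled += int(bad.sum())
        if n_resampled > max_resample:
            raise ValidationError(
                f"spawner resampling exceeded {max_resample} draws under these "
                "parameters"
            )
        S[bad] = np.exp(m + rng.normal(0.0, spawner_log_sd, size=int(bad.sum())))

    p = rng.uniform(lo, hi, size=n_years)
    eta = rng.normal(0.0, noise_sd, size=n_years) if noise_sd > 0 else np.zeros(n_years)
    log_P = dp.log_rps(S) + beta_true * p + eta
    P = np.exp(log_P)

    series = pd.DataFrame(
        {
            "year": np.arange(n_years) + first_year,
            "spawners": S,
            "recruits": S * P,
            "productivity": P,
            "log_productivity": log_P,
            "prop_captive": p,
            "residual": np.nan,
        }
    )
    truth = SimulationTruth(
        config=None,
        beta_true=beta_true,
        extra={
            "noise_sd": noise_sd,
            "density_params": asdict(dp),
            "intrusion_range": (lo, hi),
            "mean_spawners": mean_spawners,
            "spawner_log_sd": spawner_log_sd,
            "spawner_autocorr": spawner_autocorr,
            "n_resampled": n_resampled,
        },
    )
    return SeriesBundle(series, truth)
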