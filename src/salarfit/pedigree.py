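"""Lifetime reproductive success (LRS) from a reconstructed pedigree.

The unit of analysis is the *potential spawner*: an adult fish trapped on its
return from the sea, with known provenance (wild-bred vs captive-bred,
i.e. hatchery-reared and released as a smolt), sex, return year and sea age
(grilse = one sea-winter, MSW = multi-sea-winter).  LRS of a fish is the
number of distinct adult offspring genetically assigned to it in the
parentage table.  Fish with no assigned offspring have an explicit LRS of 0 —
zero fitness is data, not missingness.

Tables are plain :class:`pandas.DataFrame` objects with documented column
schemas (see :data:`FISH_COLUMNS`, :data:`PARENTAGE_COLUMNS`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import OrphanParentError, SchemaError

logger = logging.getLogger(__name__)

#: Required columns of a fish metadata table.
FISH_COLUMNS = ("fish_id", "provenance", "sex", "return_year", "sea_age")
#: Optional columns of a fish metadata table.
FISH_OPTIONAL_COLUMNS = ("fork_length", "trap_direction")
#: Required columns of a parentage-link table.
PARENTAGE_COLUMNS = ("offspring_id", "parent_id")

PROVENANCES = ("wild", "captive")


@dataclass
class ParentageTable:
    """Offspring -> parent links plus pedigree-level metadata.

    Parameters
    ----------
    links : DataFrame
        One row per (offspring_id, parent_id) link; no duplicate pairs.
    epsilon : float
        Pedigree-wide parentage assignment error rate, in [0, 1).
    n_offspring_sampled : int
        Number of candidate offspring that were tissue-sampled (the pool the
        links were drawn from), used by the bias-corrected mean-LRS estimator.
    """

    links: pd.DataFrame
    epsilon: float = 0.0
    n_offspring_sampled: int | None = None

    def __post_init__(self) -> None:
        validate_parentage(self.links)
        if not 0.0 <= self.epsilon < 1.0:
            raise SchemaError(f"epsilon must be in [0, 1), got {self.epsilon}")

    @property
    def n_links(self) -> int:
        return len(self.links)


def validate_fish(fish: pd.DataFrame) -> pd.DataFrame:
    """Check the fish metadata schema; return the (unchanged) frame."""
    missing = [c for c in FISH_COLUMNS if c not in fish.columns]
    if missing:
        raise SchemaError(f"fish table is missing required column(s): {missing}")
    dup = fish["fish_id"][fish["fish_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate fish_id values: {sorted(set(dup))[:10]}")
    bad_prov = set(fish["provenance"].unique()) - set(PROVENANCES)
    if bad_prov:
        raise SchemaError(
            f"unknown provenance value(s) {sorted(bad_prov)}; expected {PROVENANCES}"
        )
    return fish


def validate_parentage(links: pd.DataFrame) -> pd.DataFrame:
    """Check the parentage-link schema; return the (unchanged) frame."""
    missing = [c for c in PARENTAGE_COLUMNS if c not in links.columns]
    if missing:
        raise SchemaError(f"parentage table is missing required column(s): {missing}")
    if links.duplicated(subset=["offspring_id", "parent_id"]).any():
        raise SchemaError("parentage table contains duplicate (offspring, parent) pairs")
    return links


def assign_spawning_cohorts(
    fish: pd.DataFrame,
    overrides: Mapping[str, Sequence[int] | Mapping[int, float]] | None = None,
) -> pd.DataFrame:
    """Attribute each potential spawner to one or more spawning cohorts.

    Salmon return from the ocean in summer but spawn in the following winter,
    so the default rule indexes a fish returning in calendar year ``t`` to
    spawning cohort ``t``.  Fish with non-standard life histories (repeat
    spawners, delayed spawning) are handled by explicit per-fish ``overrides``:
    either a list of cohort years (equal weights) or a ``{year: weight}``
    mapping; weights are normalised to sum to one.

    Fish whose cohort cannot be resolved (missing return year, no override)
    are dropped; the count of exclusions is logged.

    Returns a copy of ``fish`` with two added columns: ``spawning_cohorts``
    (list of int years) and ``cohort_weights`` (list of floats summing to 1).
    """
    validate_fish(fish)
    overrides = overrides or {}
    out = fish.copy()
    cohorts: list[list[int] | None] = []
    weights: list[list[float] | None] = []
    n_excluded = 0
    for fid, ret in zip(out["fish_id"], out["return_year"]):
        if fid in overrides:
            entry = overrides[fid]
            if isinstance(entry, Mapping):
                yrs = [int(y) for y in entry]
                w = np.asarray([float(entry[y]) for y in entry], dtype=float)
            else:
                yrs = [int(y) for y in entry]
                w = np.ones(len(yrs))
            if len(yrs) == 0 or w.sum() <= 0:
                raise SchemaError(f"override for fish {fid!r} is empty or non-positive")
            cohorts.append(yrs)
            weights.append(list(w / w.sum()))
        elif pd.notna(ret):
            cohorts.append([int(ret)])
            weights.append([1.0])
        else:
            cohorts.append(None)
            weights.append(None)
            n_excluded += 1
    out["spawning_cohorts"] = cohorts
    out["cohort_weights"] = weights
    if n_excluded:
        logger.warning(
            "assign_spawning_cohorts: excluded %d fish with no resolvable cohort",
            n_excluded,
        )
        out = out[out["spawning_cohorts"].notna()].reset_index(drop=True)
    return out


def compute_lrs(
    parentage: ParentageTable | pd.DataFrame, fish: pd.DataFrame
) -> pd.DataFrame:
    """Count assigned adult offspring per potential spawner.

    LRS(fish) = number of *distinct* offspring linked to that fish.  A
    two-parent offspring contributes 1 to each parent's LRS.  Every fish in
    ``fish`` appears in the result; fish without links get an explicit 0.

    Raises
    ------
    OrphanParentError
        If any parent id in the links is absent from the fish table.
    """
    links = parentage.links if isinstance(parentage, ParentageTable) else parentage
    validate_parentage(links)
    validate_fish(fish)
    known = set(fish["fish_id"])
    orphans = set(links["parent_id"]) - known
    if orphans:
        raise OrphanParentError(orphans)
    counts = (
        links.drop_duplicates(subset=["offspring_id", "parent_id"])
        .groupby("parent_id")
        .size()
    )
    lrs = fish[["fish_id"]].copy()
    lrs["lrs"] = lrs["fish_id"].map(counts).fillna(0).astype(int)
    return lrs


class PairTypeSummary(NamedTuple):
    """Mating-pair outcome tables (offspring with both parents assigned)."""

    by_pair: pd.DataFrame  # index pair_class in {CC, CW, WW}
    by_n_captive_parents: pd.DataFrame  # index n_captive_parents in {0, 1, 2}


def pair_type_summary(
    parentage: ParentageTable | pd.DataFrame,
    fish: pd.DataFrame,
    lrs: pd.DataFrame,
) -> PairTypeSummary:
    """Summarise offspring of known mating pairs by parental provenance.

    Restricted to offspring with exactly two assigned parents.  Offspring are
    classed by the provenance pair of their parents (CC = captive x captive,
    CW = captive x wild, WW = wild x wild), equivalently by the number of
    captive parents (2, 1, 0).  For each class the tables give the offspring
    count, the proportion of two-parent offspring, and the mean LRS of those
    offspring (their own adult offspring counts, i.e. grand-offspring of the
    pair) where the offspring themselves appear in ``lrs``.
    """
    links = parentage.links if isinstance(parentage, ParentageTable) else parentage
    validate_parentage(links)
    prov = fish.set_index("fish_id")["provenance"]
    lrs_map = lrs.set_index("fish_id")["lrs"]

    per_off = links.groupby("offspring_id")["parent_id"].apply(list)
    two_parent = per_off[per_off.map(len) == 2]
    if len(two_parent) == 0:
        warnings.warn("no offspring with two assigned parents; empty pair summary")
        empty = pd.DataFrame(
            columns=["n_offspring", "proportion", "mean_offspring_lrs", "n_with_lrs"]
        )
        return PairTypeSummary(empty, empty.copy())

    n_captive = two_parent.map(
        lambda parents: int(sum(prov.get(p) == "captive" for p in parents))
    )
    pair_class = n_captive.map({0: "WW", 1: "CW", 2: "CC"})
    off_lrs = two_parent.index.to_series().map(lrs_map)

    def _table(group_keys: pd.Series, order: list) -> pd.DataFrame:
        df = pd.DataFrame({"key": group_keys, "lrs": off_lrs.to_numpy()})
        g = df.groupby("key")
        tab = pd.DataFrame(
            {
                "n_offspring": g.size(),
                "mean_offspring_lrs": g["lrs"].mean(),
                "n_with_lrs": g["lrs"].count(),
            }
        ).reindex([k for k in order if k in set(group_keys)])
        tab.insert(1, "proportion", tab["n_offspring"] / tab["n_offspring"].sum())
        return tab

    return PairTypeSummary(
        by_pair=_table(pair_class, ["CC", "CW", "WW"]),
        by_n_captive_parents=_table(n_captive, [0, 1, 2]),
    )
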