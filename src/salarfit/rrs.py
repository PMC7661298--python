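"""Relative reproductive success (RRS) inference for captive- vs wild-bred fish.

RRS of the captive-bred group in a spawning cohort is its mean LRS divided by
the wild-bred mean LRS, so wild-bred fish have RRS = 1 by construction.  Raw
mean LRS is biased by incomplete offspring sampling combined with parentage
assignment error; :func:`unbiased_mean_lrs` applies the standard correction

    corrected = raw_mean - ((S - A) / N) * (eps / (1 - eps))

where S is the number of offspring sampled, A the number successfully
assigned, N the number of potential parents and eps the pedigree-wide
assignment-error rate.  The correction is applied separately per provenance.

Cohort-level significance comes from one-tailed permutation tests of the
difference in mean LRS (a-priori direction: captive below wild); cohort
p-values are combined across cohorts with Fisher's combined probability test
(-2 * sum(ln p) ~ chi-squared with 2k df).  The overall RRS across cohorts is
a weighted geometric mean of cohort estimates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedRRSError, ValidationError
from .pedigree import ParentageTable, validate_parentage

logger = logging.getLogger(__name__)

_TieRule = Literal["strict", "weak"]


# ---------------------------------------------------------------------------
# bias-corrected mean LRS and RRS ratios
# ---------------------------------------------------------------------------

def unbiased_mean_lrs(
    raw_mean: float,
    n_offspring_sampled: int,
    n_offspring_assigned: int,
    n_parents: int,
    epsilon: float,
    *,
    clamp: bool = False,
) -> float:
    """Bias-corrected mean LRS for one provenance in one cohort.

    Subtracts the expected number of false assignments per potential parent:
    the unassigned offspring count (S - A), divided by the number of potential
    parents N, scaled by eps / (1 - eps).  At eps = 0 or S = A this is the
    identity.

    The corrected mean can be negative under extreme error rates; by default
    it is reported as-is (with a warning) so the estimator stays unbiased.
    Set ``clamp=True`` to truncate at zero.
    """
    S, A, N = n_offspring_sampled, n_offspring_assigned, n_parents
    if not np.isfinite(raw_mean):
        raise ValidationError(f"raw_mean must be finite, got {raw_mean}")
    if N < 1:
        raise ValidationError(f"n_parents must be >= 1, got {N}")
    if not 0.0 <= epsilon < 1.0:
        raise ValidationError(f"epsilon must be in [0, 1), got {epsilon}")
    if A > S:
        raise ValidationError(f"assigned ({A}) exceeds sampled ({S})")
    if A < 0 or S < 0:
        raise ValidationError("offspring counts must be non-negative")
    corrected = raw_mean - ((S - A) / N) * (epsilon / (1.0 - epsilon))
    if corrected < 0:
        warnings.warn(
            f"corrected mean LRS is negative ({corrected:.4g}); "
            "the correction exceeded the raw mean"
        )
        if clamp:
            corrected = 0.0
    return corrected


def cohort_rrs(corrected_captive: float, corrected_wild: float, cohort=None) -> float:
    """Captive corrected mean LRS over wild corrected mean LRS."""
    if corrected_wild <= 0:
        raise UndefinedRRSError(
            f"wild corrected mean LRS is {corrected_wild:.4g} <= 0"
            + (f" in cohort {cohort}" if cohort is not None else "")
            + "; RRS is undefined"
        )
    return corrected_captive / corrected_wild


def overall_rrs(
    rrs_by_cohort: Sequence[float], weights: Sequence[float]
) -> float:
    """Weighted geometric mean of cohort RRS estimates.

    Cohorts with non-positive RRS cannot enter a geometric mean (ln 0 is
    undefined) and are excluded with a loud warning.
    """
    r = np.asarray(rrs_by_cohort, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.shape != w.shape:
        raise ValidationError("rrs_by_cohort and weights must have equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be positive and finite")
    keep = r > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} cohort(s) with non-positive RRS "
            "from the weighted geometric mean"
        )
    if not keep.any():
        raise ValidationError("no cohort with positive RRS; geometric mean undefined")
    r, w = r[keep], w[keep]
    return float(np.exp(np.sum(w * np.log(r)) / np.sum(w)))


def mixed_population_reduction(
    n_captive_by_cohort: Sequence[float],
    rrs_by_cohort: Sequence[float],
    n_wild_by_cohort: Sequence[float],
) -> float:
    """Percent reduction in mean LRS of the mixed population vs pure wild.

    Each cohort's captive count is weighted by its RRS (wild counts by 1);
    the products are summed over cohorts, divided by the grand total of fish,
    subtracted from one and multiplied by 100.
    """
    n_c = np.asarray(n_captive_by_cohort, dtype=float)
    r = np.asarray(rrs_by_cohort, dtype=float)
    n_w = np.asarray(n_wild_by_cohort, dtype=float)
    if not (n_c.shape == r.shape == n_w.shape):
        raise ValidationError("cohort count/RRS vectors must have equal length")
    total = n_c.sum() + n_w.sum()
    if total <= 0:
        raise ValidationError("no fish in any cohort")
    return float(100.0 * (1.0 - (np.sum(n_c * r) + np.sum(n_w)) / total))


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

class PermutationResult(NamedTuple):
    observed_diff: float  #: mean(wild) - mean(captive)
    p: float
    n_perm: int  #: permutations drawn (or enumerated arrangements)
    tie_rule: str
    exact: bool


def permutation_test(
    lrs_captive: Sequence[float],
    lrs_wild: Sequence[float],
    n_perm: int = 1_000_000,
    tie_rule: _TieRule = "weak",
    seed: int | np.random.Generator | None = None,
    *,
    exact: bool = False,
    batch_size: int = 200_000,
) -> PermutationResult:
    """One-tailed permutation test of mean LRS, captive below wild.

    The observed statistic is mean(wild) - mean(captive); group labels are
    permuted jointly and the one-tailed p is the proportion of permuted
    differences exceeding the observed one.

    tie_rule='strict' counts strict exceedances over the n_perm Monte-Carlo
    draws (p can be 0); 'weak' counts ties and includes the observed
    arrangement, p = (1 + #{perm >= obs}) / (1 + n_perm), never 0.  With
    ``exact=True`` all distinct label arrangements are enumerated instead and
    p is the exact tail proportion (#{> obs}/M strict, #{>= obs}/M weak —
    the observed arrangement is one of the M).
    """
    x_c = np.asarray(lrs_captive, dtype=float)
    x_w = np.asarray(lrs_wild, dtype=float)
    if x_c.size == 0 or x_w.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not exact and n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = float(x_w.mean() - x_c.mean())
    pooled = np.concatenate([x_w, x_c])
    n, n_w = pooled.size, x_w.size
    if np.ptp(pooled) == 0:
        warnings.warn("pooled LRS values are constant; permutation test is degenerate")

    # mean(wild) - mean(captive) as an affine function of the wild-group sum
    total = pooled.sum()
    scale = 1.0 / n_w + 1.0 / x_c.size
    offset = -total / x_c.size
    # small numerical slack so ties are counted as ties
    tol = 1e-9 * max(1.0, float(np.abs(pooled).max())) * scale

    if exact:
        diffs = np.fromiter(
            (scale * sum(c) + offset for c in combinations(pooled, n_w)),
            dtype=float,
            count=math.comb(n, n_w),
        )
        # combinations of values over-counts arrangements unevenly only when
        # values tie, but tied values give identical diffs, so the tail
        # proportion over index-combinations equals the arrangement proportion
        m = diffs.size
        n_gt = int(np.sum(diffs > observed + tol))
        n_ge = int(np.sum(diffs >= observed - tol))
        p = n_gt / m if tie_rule == "strict" else n_ge / m
        return PermutationResult(observed, float(p), m, tie_rule, True)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_gt = n_ge = 0
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        perm = rng.permuted(np.broadcast_to(pooled, (b, n)), axis=1)
        diffs = scale * perm[:, :n_w].sum(axis=1) + offset
        n_gt += int(np.sum(diffs > observed + tol))
        n_ge += int(np.sum(diffs >= observed - tol))
        done += b
    if tie_rule == "strict":
        p = n_gt / n_perm
    else:
        p = (1 + n_ge) / (1 + n_perm)
    return PermutationResult(observed, float(p), n_perm, tie_rule, False)


def zero_excluded_rrs(
    lrs_captive: Sequence[float],
    lrs_wild: Sequence[float],
    n_perm: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
    tie_rule: _TieRule = "weak",
) -> tuple[float, float]:
    """RRS and permutation p restricted to fish with LRS > 0.

    Separates the zero-inflation pathway (never spawning) from the
    conditional fitness of successful spawners.  No assignment-error
    correction is applied to the filtered subset: the correction is defined
    for the full sampled offspring pool, not a success-conditioned one.
    """
    x_c = np.asarray(lrs_captive, dtype=float)
    x_w = np.asarray(lrs_wild, dtype=float)
    x_c, x_w = x_c[x_c > 0], x_w[x_w > 0]
    if x_c.size == 0 or x_w.size == 0:
        raise ValidationError("a group has no positive-LRS records")
    rrs = float(x_c.mean() / x_w.mean())
    res = permutation_test(x_c, x_w, n_perm=n_perm, tie_rule=tie_rule, seed=seed)
    return rrs, res.p


def zero_lrs_proportion_test(
    n_zero_captive: int,
    n_captive: int,
    n_zero_wild: int,
    n_wild: int,
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sample test that captive-bred fish have more zero-LRS records.

    Chi-squared test on the 2x2 table of zero vs non-zero LRS by provenance
    (Yates continuity correction optional), with the one-sided p taken in the
    captive-higher direction via the signed square root of chi2.
    Returns (chi2, one_sided_p).
    """
    if not (0 <= n_zero_captive <= n_captive and 0 <= n_zero_wild <= n_wild):
        raise ValidationError("zero counts must lie within group totals")
    if n_captive == 0 or n_wild == 0:
        raise ValidationError("group totals must be positive")
    table = np.array(
        [
            [n_zero_captive, n_captive - n_zero_captive],
            [n_zero_wild, n_wild - n_zero_wild],
        ],
        dtype=float,
    )
    if table.sum(axis=0).min() == 0:  # a margin is empty: no information
        return 0.0, 0.5
    chi2 = float(stats.chi2_contingency(table, correction=continuity)[0])
    direction = np.sign(n_zero_captive / n_captive - n_zero_wild / n_wild)
    z = direction * math.sqrt(chi2)
    return chi2, float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Fisher's combined probability test
# ---------------------------------------------------------------------------

@dataclass
class CombinedTest:
    """Fisher's combined probability test over cohort p-values."""

    chi2: float
    df: int
    p: float
    substitutions: list = field(default_factory=list)


def fisher_combined(
    p_values: Sequence[float],
    zero_policy: Literal["error", "substitute"] = "substitute",
    n_perm: int | None = None,
    alternatives: Sequence[float] | None = None,
) -> CombinedTest:
    """Combine independent one-tailed p-values: chi2 = -2 sum(ln p), df = 2k.

    A permutation p of exactly zero has an undefined logarithm.  With
    ``zero_policy='substitute'`` each zero is replaced by the permutation
    floor 1/(n_perm + 1); if a user-supplied alternative p for that position
    is given (``alternatives``), the *larger* (more conservative) of the two
    candidates is used.  Substitutions are logged in the result.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("p_values must be non-empty")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("all p-values must lie in [0, 1]")
    substitutions = []
    if np.any(p == 0):
        if zero_policy == "error":
            raise ValidationError("zero p-value with zero_policy='error'")
        if n_perm is None:
            raise ValidationError(
                "zero p-value substitution requires n_perm (the permutation floor "
                "is 1/(n_perm + 1))"
            )
        floor = 1.0 / (n_perm + 1)
        p = p.copy()
        for i in np.flatnonzero(p == 0):
            candidate = floor
            if alternatives is not None and alternatives[i] is not None:
                candidate = max(candidate, float(alternatives[i]))
            substitutions.append({"index": int(i), "substituted_p": candidate})
            p[i] = candidate
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return CombinedTest(chi2, df, float(stats.chi2.sf(chi2, df)), substitutions)


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def sampling_tallies(
    fish: pd.DataFrame,
    parentage: ParentageTable | pd.DataFrame,
    cohorts: Sequence[int],
    lags: tuple[int, int] = (4, 5),
) -> pd.DataFrame:
    """Per-cohort sampled/assigned offspring tallies for the bias correction.

    The candidate (sampled) offspring pool of spawning cohort t is the set of
    wild-bred fish in the sampled fish table returning as grilse in year
    t + lags[0] or as MSW fish in year t + lags[1].  A_provenance is the
    number of those offspring assigned to at least one parent of that
    provenance spawning in cohort t.
    """
    links = parentage.links if isinstance(parentage, ParentageTable) else parentage
    validate_parentage(links)
    member_cohort = _cohort_membership(fish)
    parent_prov = fish.set_index("fish_id")["provenance"]
    rows = []
    for t in cohorts:
        grilse = (
            (fish["provenance"] == "wild")
            & (fish["return_year"] == t + lags[0])
            & (fish["sea_age"] == "grilse")
        )
        msw = (
            (fish["provenance"] == "wild")
            & (fish["return_year"] == t + lags[1])
            & (fish["sea_age"] == "MSW")
        )
        candidates = set(fish.loc[grilse | msw, "fish_id"])
        sub = links[links["offspring_id"].isin(candidates)]
        in_cohort = sub["parent_id"].map(
            lambda p, t=t: t in member_cohort.get(p, ())
        )
        sub = sub[in_cohort.astype(bool)]
        assigned = sub.groupby(sub["parent_id"].map(parent_prov))["offspring_id"].nunique()
        rows.append(
            {
                "cohort": t,
                "n_offspring_sampled": len(candidates),
                "n_assigned_captive": int(assigned.get("captive", 0)),
                "n_assigned_wild": int(assigned.get("wild", 0)),
            }
        )
    return pd.DataFrame(rows)


def _cohort_membership(fish: pd.DataFrame) -> dict:
    """fish_id -> tuple of spawning cohort years (falls back to return_year)."""
    if "spawning_cohorts" in fish.columns:
        return {
            fid: tuple(c)
            for fid, c in zip(fish["fish_id"], fish["spawning_cohorts"])
            if c is not None
        }
    return {
        fid: (int(y),)
        for fid, y in zip(fish["fish_id"], fish["return_year"])
        if pd.notna(y)
    }


def cohort_fitness_table(
    fish: pd.DataFrame,
    lrs: pd.DataFrame,
    parentage: ParentageTable | pd.DataFrame,
    cohorts: Sequence[int],
    epsilon: float | None = None,
    n_perm: int = 100_000,
    tie_rule: _TieRule = "weak",
    seed: int | np.random.Generator | None = None,
    sex: str | None = None,
    lags: tuple[int, int] = (4, 5),
    tallies: pd.DataFrame | None = None,
    n_scope: Literal["provenance", "pooled"] = "provenance",
) -> pd.DataFrame:
    """Cohort-by-cohort corrected mean LRS, RRS and permutation p.

    One row per spawning cohort with per-provenance parent counts, raw and
    bias-corrected mean LRS, the cohort RRS (captive / wild) and the
    one-tailed permutation p-value.  ``sex`` restricts the comparison to one
    sex ('F' or 'M'); fish of unknown sex are excluded from sex-specific runs
    only.  ``n_scope`` selects whether N in the correction is the
    per-provenance parent count (default) or the pooled count.
    """
    if epsilon is None:
        epsilon = parentage.epsilon if isinstance(parentage, ParentageTable) else 0.0
    if tallies is None:
        tallies = sampling_tallies(fish, parentage, cohorts, lags=lags)
    tallies = tallies.set_index("cohort")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lrs_map = lrs.set_index("fish_id")["lrs"]
    member_cohort = _cohort_membership(fish)

    rows = []
    for t in cohorts:
        members = fish[[t in member_cohort.get(f, ()) for f in fish["fish_id"]]]
        if sex is not None:
            members = members[members["sex"] == sex]
        vals = {
            g: lrs_map.loc[members.loc[members["provenance"] == g, "fish_id"]].to_numpy()
            for g in ("captive", "wild")
        }
        n_c, n_w = len(vals["captive"]), len(vals["wild"])
        if n_c == 0 or n_w == 0:
            logger.warning("cohort %s has an empty provenance group; skipped", t)
            continue
        S = int(tallies.loc[t, "n_offspring_sampled"])
        row = {"cohort": t, "n_captive": n_c, "n_wild": n_w}
        corrected = {}
        for g, n_g in (("captive", n_c), ("wild", n_w)):
            raw = float(vals[g].mean())
            A = min(int(tallies.loc[t, f"n_assigned_{g}"]), S)
            N = n_c + n_w if n_scope == "pooled" else n_g
            corrected[g] = unbiased_mean_lrs(raw, S, A, N, epsilon)
            row[f"raw_mean_{g}"] = raw
            row[f"corrected_mean_{g}"] = corrected[g]
        row["rrs"] = cohort_rrs(corrected["captive"], corrected["wild"], cohort=t)
        res = permutation_test(
            vals["captive"], vals["wild"], n_perm=n_perm, tie_rule=tie_rule, seed=rng
        )
        row["observed_diff"] = res.observed_diff
        row["perm_p"] = res.p
        row["n_perm"] = res.n_perm
        rows.append(row)
    return pd.DataFrame(rows)
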