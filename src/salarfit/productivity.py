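"""Population productivity and its relationship to hatchery intrusion.

Whole-life-cycle productivity of spawning cohort t is adult recruits per
spawner: wild-bred grilse returning in year t+4 plus wild-bred MSW fish
returning in year t+5 (all wild recruits assumed to smolt at age 2+), divided
by the total number of potential spawners (wild + captive) in year t.

Density dependence is removed without committing to a parametric
stock-recruitment form: log productivity is regressed on spawner numbers with
a penalized cubic regression spline (basis dimension 9, smoothing parameter
by generalized cross-validation).  The residuals are a density-independent
productivity index, which is then regressed by OLS on the annual proportion
of potential spawners that were captive-bred ("hatchery intrusion").  A
negative slope beta translates into a percent productivity reduction
100 * (1 - exp(beta * x)) at intrusion level x.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.smooth_basis import BSplines

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Required columns of a census table (one row per year x provenance x sea age).
CENSUS_COLUMNS = ("year", "provenance", "sea_age", "count")

SERIES_COLUMNS = (
    "year",
    "spawners",
    "recruits",
    "productivity",
    "log_productivity",
    "prop_captive",
    "residual",
)


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise SchemaError(f"census table is missing required column(s): {missing}")
    if (census["count"] < 0).any():
        raise SchemaError("census counts must be non-negative")
    return census


# ---------------------------------------------------------------------------
# productivity series
# ---------------------------------------------------------------------------

def recruits_per_spawner(
    census: pd.DataFrame,
    t_range: Sequence[int] | None = None,
    lags: tuple[int, int] = (4, 5),
    zero_policy: Literal["drop", "offset"] = "drop",
    zero_offset: float = 0.5,
) -> pd.DataFrame:
    """Adult-to-adult productivity series from an annual census.

    For each spawning-cohort year t with complete life-cycle coverage
    (census span includes t + lags[1]), productivity P_t is

        (wild grilse at t+lags[0] + wild MSW at t+lags[1]) / spawners at t

    with spawners = all potential spawners (both provenances) in year t.
    Years with zero spawners are excluded with a warning.  Years with zero
    recruits have undefined log productivity; by default they are dropped
    (``zero_policy='drop'``), or a small count offset can be added
    (``zero_policy='offset'``), which is logged.
    """
    validate_census(census)
    by_year = census.groupby("year")["count"].sum()
    captive_by_year = (
        census[census["provenance"] == "captive"].groupby("year")["count"].sum()
    )

    wild = census[census["provenance"] == "wild"]
    grilse = wild[wild["sea_age"] == "grilse"].groupby("year")["count"].sum()
    msw = wild[wild["sea_age"] == "MSW"].groupby("year")["count"].sum()

    span_max = int(census["year"].max())
    if t_range is None:
        t_range = [int(t) for t in by_year.index if t + lags[1] <= span_max]
    else:
        t_range = [int(t) for t in t_range]
        uncovered = [t for t in t_range if t + lags[1] > span_max]
        if uncovered:
            logger.warning(
                "excluding %d year(s) without complete t+%d/t+%d recruit coverage",
                len(uncovered), lags[0], lags[1],
            )
            t_range = [t for t in t_range if t not in set(uncovered)]

    rows = []
    n_zero_spawners = n_zero_recruits = 0
    for t in t_range:
        S = float(by_year.get(t, 0.0))
        if S <= 0:
            n_zero_spawners += 1
            continue
        R = float(grilse.get(t + lags[0], 0.0)) + float(msw.get(t + lags[1], 0.0))
        P = R / S
        if R <= 0:
            n_zero_recruits += 1
            if zero_policy == "drop":
                continue
            P = (R + zero_offset) / S
        rows.append(
            {
                "year": t,
                "spawners": S,
                "recruits": R,
                "productivity": P,
                "log_productivity": float(np.log(P)),
                "prop_captive": float(captive_by_year.get(t, 0.0)) / S,
                "residual": np.nan,
            }
        )
    if n_zero_spawners:
        warnings.warn(f"excluded {n_zero_spawners} year(s) with zero spawners")
    if n_zero_recruits:
        warnings.warn(
            f"{n_zero_recruits} year(s) with zero recruits "
            + ("dropped" if zero_policy == "drop" else f"offset by {zero_offset}")
        )
    return pd.DataFrame(rows, columns=list(SERIES_COLUMNS))


@dataclass
class FecundityModel:
    """Log-linear length-fecundity relationship: ln(eggs) = a + b ln(length).

    The package ships no empirical coefficients — fecundity-length data for a
    given system must be supplied explicitly.  ``synthetic_default`` provides
    a literature-style shape for synthetic-data tests only.  Captive-bred
    females carry a fecundity multiplier (default 1.4, i.e. more eggs per
    female than wild-bred fish of the same length).
    """

    log_a: float | None = None
    b: float | None = None
    captive_multiplier: float = 1.4

    def eggs(self, length_cm, provenance: str = "wild") -> np.ndarray:
        if self.log_a is None or self.b is None:
            raise ValidationError(
                "FecundityModel coefficients are unset; supply log_a and b "
                "explicitly (no empirical default ships with the package)"
            )
        e = np.exp(self.log_a + self.b * np.log(np.asarray(length_cm, dtype=float)))
        if np.any(np.asarray(length_cm) <= 0):
            raise ValidationError("lengths must be positive")
        if provenance == "captive":
            e = e * self.captive_multiplier
        return e

    @classmethod
    def synthetic_default(cls) -> "FecundityModel":
        """Synthetic coefficients (not an empirical calibration): ~1200 eggs
        for a 62 cm grilse, scaling with length^2.2."""
        return cls(log_a=-2.0, b=2.2, captive_multiplier=1.4)


def ova_productivity(
    census: pd.DataFrame,
    fecundity: FecundityModel,
    t_range: Sequence[int] | None = None,
    lags: tuple[int, int] = (4, 5),
    prop_female: float = 0.5,
    zero_policy: Literal["drop", "offset"] = "drop",
) -> pd.DataFrame:
    """Ova-per-ovum productivity: adults converted to eggs before the ratio.

    Each census row must carry a ``mean_length`` (cm) for its year x
    provenance x sea-age class.  Egg totals are count x prop_female x
    predicted eggs at the class mean length (captive rows get the captive
    fecundity multiplier).  Productivity is recruit-side eggs (wild grilse at
    t+4, wild MSW at t+5) per spawner-side egg at t; ``prop_captive`` is the
    captive share of spawner-side eggs.
    """
    validate_census(census)
    if "mean_length" not in census.columns:
        raise SchemaError("ova_productivity requires a 'mean_length' census column")
    c = census.copy()
    c["eggs"] = [
        cnt * prop_female * float(fecundity.eggs(L, prov))
        for cnt, L, prov in zip(c["count"], c["mean_length"], c["provenance"])
    ]
    egg_census = c[["year", "provenance", "sea_age"]].copy()
    egg_census["count"] = c["eggs"]
    return recruits_per_spawner(
        egg_census, t_range=t_range, lags=lags, zero_policy=zero_policy
    )


# ---------------------------------------------------------------------------
# density correction (penalized spline GAM)
# ---------------------------------------------------------------------------

@dataclass
class GAMFit:
    """Penalized-spline fit of log productivity on spawner numbers."""

    k: int  #: basis dimension (number of knots)
    alpha: float  #: selected smoothing parameter
    criterion: str  #: smoothing selection criterion
    gcv: float
    edf: float  #: effective degrees of freedom (trace of the hat matrix)
    fitted: np.ndarray
    residuals: np.ndarray
    years: np.ndarray  #: years entering the fit (complete rows only)
    basis: str = "cubic regression B-spline"


def fit_density_gam(
    series: pd.DataFrame,
    k: int = 9,
    criterion: str = "gcv",
    alphas: np.ndarray | None = None,
) -> GAMFit:
    """Density-correct log productivity with a k-knot penalized spline.

    Fits log P_t = f(S_t) + e_t where f is a cubic B-spline with basis
    dimension ``k`` and a derivative penalty; the smoothing parameter is
    chosen by generalized cross-validation over a log-spaced grid.  The
    penalty null space contains constants and linear trends, so constant or
    exactly-linear series are reproduced to machine precision at any alpha.
    Residuals are the density-independent productivity index.
    """
    if criterion != "gcv":
        raise ValidationError(f"unsupported smoothing criterion {criterion!r}")
    use = series.dropna(subset=["spawners", "log_productivity"])
    y = use["log_productivity"].to_numpy(dtype=float)
    x = use["spawners"].to_numpy(dtype=float)
    n = len(y)
    if n < k + 2:
        raise InsufficientDataError(
            f"need at least k + 2 = {k + 2} usable years, got {n}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError("spawner numbers are constant; spline undefined")

    # df=k with include_intercept=False yields k-1 columns; with the explicit
    # intercept the total basis dimension is k
    bs = BSplines(x[:, None], df=[k], degree=[3], include_intercept=False)
    B = bs.basis
    X = np.column_stack([np.ones(n), B])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            f"rank-deficient {GAMFit.basis} basis (dimension {k}) on these data"
        )
    P = np.zeros((X.shape[1], X.shape[1]))
    P[1:, 1:] = bs.penalty_matrices[0]

    if alphas is None:
        alphas = np.logspace(-8, 12, 81)
    xtx, xty = X.T @ X, X.T @ y
    best = None
    for a in alphas:
        A = xtx + a * P
        beta = np.linalg.solve(A, xty)
        edf = float(np.trace(np.linalg.solve(A, xtx)))
        rss = float(((y - X @ beta) ** 2).sum())
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, a, beta, edf)
    gcv, alpha, beta, edf = best
    fitted = X @ beta
    return GAMFit(
        k=k,
        alpha=float(alpha),
        criterion=criterion,
        gcv=float(gcv),
        edf=edf,
        fitted=fitted,
        residuals=y - fitted,
        years=use["year"].to_numpy(),
    )


def attach_residuals(series: pd.DataFrame, fit: GAMFit) -> pd.DataFrame:
    """Return a copy of the series with the GAM residual column filled."""
    out = series.copy()
    res = pd.Series(fit.residuals, index=fit.years)
    out["residual"] = out["year"].map(res)
    return out


# ---------------------------------------------------------------------------
# intrusion regression and summaries
# ---------------------------------------------------------------------------

@dataclass
class IntrusionRegression:
    """OLS of density-corrected productivity on hatchery intrusion."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int


def intrusion_regression(
    residuals: Sequence[float], prop_captive: Sequence[float]
) -> IntrusionRegression:
    """OLS slope of GAM residuals on the captive-bred spawner proportion."""
    e = np.asarray(residuals, dtype=float)
    p = np.asarray(prop_captive, dtype=float)
    if e.shape != p.shape:
        raise ValidationError("residuals and prop_captive must have equal length")
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(p))):
        raise ValidationError("inputs must be finite")
    if e.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.ptp(p) == 0:
        raise DegenerateDesignError("intrusion proportion is constant across years")
    res = sm.OLS(e, sm.add_constant(p)).fit()
    return IntrusionRegression(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df=(1, int(res.df_resid)),
        p_value=float(res.f_pvalue),
        n=e.size,
    )


def percent_reduction(beta: float, x: float) -> float:
    """Percent productivity reduction at intrusion x, back-transformed from
    the log scale: 100 * (1 - exp(beta * x))."""
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"intrusion proportion must be in [0, 1], got {x}")
    return float(100.0 * (1.0 - np.exp(beta * x)))


class CorrelationResult:
    """Pearson correlation with its t statistic: t = r sqrt(df / (1 - r^2))."""

    def __init__(self, r: float, df: int):
        self.r = float(r)
        self.df = int(df)
        if abs(self.r) >= 1.0:
            warnings.warn("|r| = 1: degenerate (perfectly linear) data")
            self.t_stat = float(np.inf) * np.sign(self.r)
            self.p = 0.0
        else:
            self.t_stat = self.r * np.sqrt(self.df / (1.0 - self.r**2))
            self.p = float(2.0 * stats.t.sf(abs(self.t_stat), self.df))

    def __iter__(self):  # (r, t, df, p) tuple-compatible
        return iter((self.r, self.t_stat, self.df, self.p))

    def __repr__(self):
        return (
            f"CorrelationResult(r={self.r:.4g}, t={self.t_stat:.4g}, "
            f"df={self.df}, p={self.p:.4g})"
        )


def density_intrusion_correlation(
    spawners: Sequence[float], prop_captive: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation between the density proxy and hatchery intrusion.

    Checks that spawner abundance (the density measure the spline removes) is
    not confounded with the intrusion predictor.  Two-sided p from the t
    distribution with n - 2 df.
    """
    s = np.asarray(spawners, dtype=float)
    p = np.asarray(prop_captive, dtype=float)
    if s.shape != p.shape or s.size < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(s) == 0 or np.ptp(p) == 0:
        raise DegenerateDesignError("zero-variance input to Pearson correlation")
    r = float(np.corrcoef(s, p)[0, 1])
    return CorrelationResult(r, s.size - 2)


def correlation_from_r(r: float, df: int) -> CorrelationResult:
    """Recompute t and p from a correlation coefficient and its df."""
    return CorrelationResult(r, df)


def regression_p_from_f(f_stat: float, df2: int) -> float:
    """Upper-tail p of F(1, df2) — the OLS slope test."""
    return float(stats.f.sf(f_stat, 1, df2))


def adj_r2_from_f(f_stat: float, df2: int) -> float:
    """Adjusted R^2 implied by F with (1, df2) df: R^2 = F/(F + df2),
    adjusted for one predictor."""
    r2 = f_stat / (f_stat + df2)
    n = df2 + 2
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def diagnostic_plots(series: pd.DataFrame, fit: GAMFit, path) -> None:
    """Write a two-panel diagnostic figure (spline fit; residuals vs intrusion)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    use = series.dropna(subset=["log_productivity"])
    order = np.argsort(use["spawners"].to_numpy())
    axes[0].scatter(use["spawners"], use["log_productivity"], s=12, color="k")
    axes[0].plot(
        use["spawners"].to_numpy()[order], fit.fitted[order], color="C1", lw=1.5
    )
    axes[0].set_xlabel("potential spawners")
    axes[0].set_ylabel("log productivity")
    sub = series.dropna(subset=["residual"])
    axes[1].scatter(sub["prop_captive"], sub["residual"], s=12, color="k")
    axes[1].axhline(0, color="grey", lw=0.8)
    axes[1].set_xlabel("proportion captive-bred")
    axes[1].set_ylabel("density-corrected residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
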