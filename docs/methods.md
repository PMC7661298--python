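# Methods

This note documents the statistical models implemented in `salarfit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Life-cycle conventions

The unit of analysis is the *potential spawner*: an adult salmon trapped on
its return from the sea, with provenance (wild-bred vs captive-bred, the
latter hatchery-reared and released as a smolt), sex, return year, sea age
(grilse = one sea-winter; MSW = multi-sea-winter) and optional fork length
and trap direction.  Fish return in summer but spawn the following winter,
so the default rule indexes a fish returning in year *t* to spawning cohort
*t*.  Non-standard life histories (repeat or delayed spawners) are handled
by explicit per-fish override entries — a list of cohort years or a
`{year: weight}` map, normalised to sum to one — rather than hard-coded
special cases.  How a repeat spawner's LRS should be split across cohorts is
not observable from a parentage table alone; the override weights record the
analyst's choice without claiming more.

Recruit accounting assumes all wild-bred fish smolt at age 2+, so the adult
recruits of cohort *t* are the wild grilse returning at *t*+4 and the wild
MSW fish at *t*+5.  The two lags are exposed as configuration for systems
with different smolt ages.  Mature male parr are outside the sampled frame;
because both provenances are affected alike, their absence shifts absolute
but not relative reproductive success.

## Bias-corrected mean LRS and RRS

Raw mean LRS per provenance and cohort is biased when sampled offspring go
unassigned and assignments carry error.  With S offspring sampled, A
assigned, N potential parents and assignment-error rate ε, the corrected
mean is

    corrected = raw − ((S − A) / N) · ε / (1 − ε)

applied separately to each provenance (N defaults to the per-provenance
parent count; a pooled-N switch exists).  The correction is the expected
number of false assignments accrued per potential parent: unassigned
offspring per parent, scaled by the odds ε/(1−ε) of a misassignment.  At
ε = 0 or S = A it is the identity; it is monotone non-increasing in ε and in
S − A.  Extreme inputs can push the corrected mean below zero; by default
the value is reported as-is with a warning (clamping would re-introduce
bias), with an optional clamp at zero.

Cohort RRS is corrected captive mean over corrected wild mean, so wild-bred
fish have RRS ≡ 1.  A non-positive wild corrected mean makes RRS undefined
and raises an error naming the cohort.

**Overall RRS** across cohorts is the weighted geometric mean
exp(Σ wᵢ ln rᵢ / Σ wᵢ).  Weights default to total fish per cohort
(captive + wild); captive-only and user-supplied weights are available and
the scheme used is recorded in the run manifest.  Cohorts with non-positive
RRS have no logarithm and are excluded with a loud warning rather than
silently imputed.

## Permutation tests and Fisher combination

Cohort significance uses a one-tailed permutation test of
mean(wild) − mean(captive), direction fixed a priori (captive below wild);
a two-sided interpretation is available by doubling externally.  Labels are
permuted jointly; two tail rules are implemented:

- `strict`: p = #{permuted diff > observed} / n_perm (can be exactly 0);
- `weak` (default): p = (1 + #{diff ≥ observed}) / (1 + n_perm), which
  counts ties, includes the observed arrangement, and can never be 0.

For small groups an exact mode enumerates all C(n, n_w) label arrangements;
there the strict/weak rules are the exact tail proportions #{> obs}/M and
#{≥ obs}/M.  Tie detection uses a relative tolerance of 1e−9 on the scale
of the data so floating-point noise cannot split a tie.  Monte-Carlo
permutations are drawn in batches (bounded memory) from a seeded
`numpy.random.Generator`.

Cohort p-values are combined with Fisher's method: χ² = −2 Σ ln pᵢ on
2k df.  A strict-rule p of exactly 0 has no logarithm; with the default
substitution policy each zero is replaced by the permutation floor
1/(n_perm + 1), and if an alternative p (e.g. from an exact test) is
supplied, the *larger* — more conservative — candidate is used.  All
substitutions are logged in the result object and the manifest.

**Zero-LRS analyses.**  Whether captive-bred fish fail to reproduce more
often is tested on the 2×2 table of zero vs non-zero LRS by provenance
(chi-squared, optional Yates correction, one-sided in the captive-higher
direction via the signed square root of χ²).  The zero-excluded RRS then
compares only fish with LRS > 0, separating the never-spawned pathway from
the conditional fitness of successful spawners.  No ε-correction is applied
to the zero-excluded subset: the correction is defined for the full sampled
offspring pool, not a success-conditioned one.

**Mixed-population reduction.**  The percent reduction in mean LRS of the
observed mixed population relative to a hypothetical all-wild one is
100·(1 − Σ(n_cᵢ·rᵢ + n_wᵢ)/Σ(n_cᵢ + n_wᵢ)) — a cohort-size-weighted
average of (1 − rᵢ) over the captive fraction.

## Density-corrected productivity

log productivity is regressed on spawner numbers with a penalized cubic
B-spline of basis dimension 9 ("nine knots"), an explicit intercept, and a
derivative penalty whose null space contains constants and linear trends.
The fit is solved directly by penalized least squares (the model is
Gaussian, so no iterative reweighting is needed); the smoothing parameter is
selected by generalized cross-validation, GCV(α) = n·RSS/(n − edf)², over a
65-point log-spaced grid from 1e−8 to 1e12, with edf the trace of the hat
matrix.  Direct solution makes degenerate inputs exact: a constant or
exactly-linear series is reproduced to machine precision at any α (both are
unpenalized), which an IRLS implementation rejects as perfect separation.
The fit is cross-checked in the test suite against `statsmodels` `GLMGam`
at the selected α on noisy data.  At least k + 2 usable years are required;
constant spawner numbers or a rank-deficient basis raise errors.

Residuals from this fit are the density-independent productivity index and
are regressed by OLS on the annual captive-bred spawner proportion.  The
two-stage (residual) regression is unbiased for the intrusion slope when
intrusion is uncorrelated with density; the package therefore also reports
the Pearson correlation between spawner numbers and intrusion
(t = r·sqrt(df/(1−r²)), df = n−2) so users can verify this assumption, as
should be done on any real series.  Zero-recruit years have undefined log
productivity and are dropped with a warning by default; an additive-offset
option exists and is logged.  The back-transformed effect size is
100·(1 − exp(β·x)) percent at intrusion x.

The ova-per-ovum variant converts adults to eggs before forming the ratio,
using a log-linear length–fecundity model ln(eggs) = a + b·ln(length) with
a captive multiplier (default 1.4 — captive-bred females carry more eggs
per capita).  The package ships **no** empirical fecundity coefficients:
the operation refuses to run until a and b are supplied, because any
default would masquerade as a calibration.  `FecundityModel.synthetic_default`
provides a synthetic, literature-style shape (~1200 eggs at 62 cm, scaling
as length^2.2) for tests only.

## Synthetic-data generator

`simulate_pedigree` draws, per focal cohort and provenance, a hurdle
offspring count per potential spawner: zero with probability π_g, else a
shifted negative-binomial 1 + NB(mean m_g − 1, dispersion θ) (gamma–Poisson
mixture).  The captive positive-part mean is set from the wild one so the
per-capita mean ratio equals the true fitness ratio ρ exactly.  Every
offspring receives an opposite-sex co-parent drawn with probability
proportional to the co-parent's own brood size; this keeps never-spawners
at LRS 0 (a fish with no offspring cannot have mated) and preserves the
per-capita provenance ratio ρ in expectation for both sexes.  Parents are
sampled with fraction f_p and offspring with f_o; only links from sampled
offspring to sampled parents are recorded, so one- vs two-parent
assignments emerge from parent sampling as in a real pedigree.  Each
recorded link is corrupted with probability ε and reassigned to a uniform
random *other* sampled parent (provenance-blind by default; a
within-provenance switch exists).  Sampled offspring then draw their own
wild-parameter broods, giving the second generation needed for mating-pair
grand-offspring summaries.  One root seed is split into per-stage
substreams (`Generator.spawn`), so outputs are byte-identical across runs
with the same seed.

Defaults describe the targeted study conditions: six cohorts; 350 wild and
82 captive spawners per cohort (~19 % captive); ρ = 0.36; zero
probabilities π_w = 0.55 and π_c = 0.80, chosen once so the implied
positive-part (zero-excluded) ratio ρ·(1−π_w)/(1−π_c) equals 0.81; wild
positive-part mean 2.2 and dispersion 0.7 (free realistic choices — the
zero-excluded ratio and overall ratio pin down only two moments); f_p = 0.5,
f_o = 0.8, ε = 0.02; 90 % grilse; balanced sex ratio; 1.4× captive fecundity.
Default cohort years are spaced seven years apart so offspring and
grand-offspring return years never alias into a focal cohort; real
consecutive-year cohorts do alias, which is a property of real data the
generator deliberately avoids in order to keep ground truth exact.

`simulate_productivity_series` draws spawner numbers from a stationary
lognormal AR(1) (mean 700, log-sd 0.5, autocorrelation 0.6), intrusion
proportions independently uniform on [0.01, 0.59], and sets
log P = log(max_rps) − log(1 + S/half-saturation) + β·p + Gaussian noise
(defaults max_rps 2.0, half-saturation 500, β = −0.686, noise sd 0.25).
Independence of S and p is a deliberate generator property: it is the
regime in which the residual method is unbiased, and it mirrors the weak
density–intrusion correlation observed in the system the analysis targets.
A generator that closed the demographic loop (captive additions inflating
the same year's density) would couple S and p and the two-stage regression
would attribute part of the intrusion effect to density; real analyses must
check the reported density–intrusion correlation before trusting the
residual slope.

What passing tests show, and what they do not: parameter recovery on these
simulations demonstrates the estimators are implemented correctly and are
unbiased *under the generating assumptions* (exchangeable fish within
provenance, provenance-blind misassignment, independent density and
intrusion, no age/sex structure in fitness).  They do not validate those
assumptions for any real river.

## Numerical and design notes

- β = −0.686 as the canonical simulator slope is the value implied by a
  9.78 % productivity reduction at intrusion 0.15 (ln(1 − 0.0978)/0.15).
- Under the generator's link-corruption mechanism with full parent
  sampling, false assignments accrue equally per parent of either
  provenance; the per-provenance correction subtracts slightly different
  amounts (A differs by provenance), so at ε = 0.02 the corrected overall
  RRS sits ~0.01 below the generating 0.36 while the raw estimator sits
  ~0.002 above it.  Both are well within the Monte-Carlo tolerance; the
  correction's value lies in the regimes where unassigned offspring are
  plentiful and asymmetric.
- Permutation p-values on heavily tied count data are conservative under
  the weak rule; the empirical size at α = 0.05 measured in the acceptance
  suite is ~0.049.
- The spline's exactness on linear series holds because linear functions
  lie in the penalty null space; smooth but non-polynomial density curves
  (e.g. Beverton–Holt) leave small residual misfit, so the "no intrusion,
  no noise" null recovers a slope near but not exactly zero (|slope| <
  1e−4 in tests).
- All file outputs avoid timestamps; reports re-run with the same seed and
  config are byte-identical.

## Known limitations

- The ε-correction treats assignment error as a single pedigree-wide
  scalar; per-provenance or per-cohort error rates are not modelled.
- No confidence intervals for RRS beyond permutation p-values.
- The generator has no age- or size-structured fitness, no temporal trend
  in ρ, and no within-river spatial structure.
- The ova-per-ovum measure uses class-mean lengths, not individual fish.
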