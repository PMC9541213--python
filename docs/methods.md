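# Methods

## Model and normalization

The package treats acclimation as relaxation of a trait toward its new
steady state. All estimation happens on the dimensionless scale
D_t = (z_t − z∞)/(z₀ − z∞), the proportion of the full plastic response
still remaining; D is invariant to affine transformations of the raw trait
(unit changes, offsets), which is what makes rates comparable across traits
and studies.

Reference values are plug-in constants resolved by policy:

* **z₀** — default: the mean shifted-group phenotype at the earliest
  post-shift time point (the first measurement in the new environment).
  Because an exponential decay rate is time-invariant, the first
  measurement need not be at any particular time after transfer; times are
  re-referenced so that it sits at t = 0, where D = 1 by construction. An
  alternative policy uses the initial-environment control mean as z₀ (for
  designs whose first shifted measurement is late or noisy); under that
  policy D(0) is a measured quantity and may differ from 1.
* **z∞** — default: the mean of the control group fully acclimated to the
  new environment. Without such a group the full response magnitude is
  unknown and the true rate cannot be estimated; the package raises a
  design error rather than guessing. An opt-in fallback (with a warning)
  uses the final shifted time point's mean, for re-analysis of legacy
  single-control studies — valid only if acclimation was complete.

D points are computed from per-time-point means by default (a
replicate-level mode exists). Noisy D values outside [0, 1] are retained
for curve fitting — clamping would bias least squares — but rejected by the
closed-form single-point estimators, whose domain is 0 < D ≤ 1.

Guard rails: normalization fails with a "no detectable plastic response"
error when |z₀ − z∞| does not exceed 0.1× the pooled within-group SD
(configurable), and warns when successive shifted means reverse direction
by more than twice their pooled standard error, since the model assumes a
unidirectional response (overshoot/homeostatic-return dynamics are out of
scope).

## Fitting and model comparison

Both response shapes have one free parameter and a fixed anchor D(0) = 1:

* exponential: D(t) = exp(−λt);
* segmented linear: D(t) = max(1 − λt, 0) — intercept fixed at 1,
  breakpoint tied to the slope at t = 1/λ, plateau at exactly 0. An
  unconstrained two-parameter broken stick is deliberately not offered: the
  single-parameter constraint is what makes the two RSEs comparable.

Each fit minimizes the residual sum of squares over λ > 0. Degrees of
freedom: RSE = √(SS/(n − 1)) with one free parameter; the anchor point
(zero residual under both models) is included in n by default, and a switch
excludes it for sensitivity analysis. The shape with the smaller RSE is
selected; |ΔRSE| ≤ 1e−9 is reported as `indistinguishable` (a
floating-point-safe tie rule). Note a documented caveat: the segmented
model's data-adaptive breakpoint gives it slightly different effective
flexibility than the exponential despite the equal parameter count; the
comparison is implemented as the RSE rule regardless, since that is the
procedure being standardized.

### Optimization

The search range for λ is taken from the closed-form single-point
estimates (their min/max, widened ×10 each way) unioned with a wide
fallback range [1e−8, 1e4]. When every point is strictly interior
(0 < D < 1) the SSE is monotone outside the point-estimate range, so the
global minimum provably lies within it; points outside (0, 1) — common in
noisy tails — break that guarantee, hence the union.

* Segmented linear: the SSE is piecewise quadratic in λ, with kinks where
  an observation crosses the plateau (λ = 1/tᵢ). The fitter enumerates the
  segments, solves each quadratic in closed form, clamps to the segment and
  takes the global best — an exact, deterministic minimizer.
* Exponential: the SSE is smooth but can be multimodal and nearly flat for
  noise-dominated series, so a deterministic coarse scan on log λ (1024
  points) locates candidate basins, a 256-point sub-scan refines the best
  few, and bounded 1-D minimization (relative tolerance 1e−10, ≤200
  iterations) polishes each; the deepest minimum wins. No random restarts:
  the whole procedure is deterministic.

Half-times: ln(2)/λ for the exponential shape. For the linear shape the
package reports 0.5/λ (the time at which 1 − λt = 0.5) as a convenience;
this is a package convention — exponential and linear rates have no common
currency and should not be compared numerically across shapes.

## Bootstrap

Nonparametric case resampling: replicates are resampled with replacement
independently within each shifted time point and within each control
group; every resample re-derives z₀, z∞ and the D series and refits, so
the percentile interval propagates reference-value uncertainty as well as
curve-fit uncertainty. Each cell of n replicates is resampled m = n − 1
times rather than n: plain n-of-n resampling understates the variance of a
cell mean by the factor (n − 1)/n — a material bias at the small replicate
counts typical of acclimation experiments — whereas m = n − 1 makes it
exactly unbiased (the m-out-of-n small-sample correction). Defaults: 1000
resamples, 95% level, percentile interval. Requires ≥ 2
replicates per shifted time point; refit failures are counted and
reported, never silently dropped. Fully reproducible given the seed.

## Synthetic data generator

`simulate_time_course` realizes the design the estimators assume: shifted
records with expectation z(t) = z∞ + (z₀ − z∞)·g(t), g the declared shape,
plus both control groups at their acclimated means, all with i.i.d.
additive Gaussian noise on the phenotype scale (homoscedastic across
groups and times — the simplest structure consistent with least squares).
Defaults: z₀ = 1, z∞ = 0, so `noise_sd` reads directly as a fraction of
the full plastic response — the scale on which measurement error actually
limits rate estimation, and one that affine invariance makes fully general.
Noise default 0.05 (5% of the response), 5 replicates per time point, 7
time points spanning three half-lives of the true rate (so z∞ is
approachable within the series); for linear-shape simulations the natural
schedule instead spans ~1.2× the completion time 1/λ so the plateau is
observable. Control groups are stamped with the shifted schedule's nominal
times purely for format realism.

What the generator does **not** emulate: heteroscedastic or autocorrelated
errors, replicate-level random effects (repeated measures on the same
individual), drifting control means, non-monotone responses, or
measurement error in time. Passing Monte-Carlo checks therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to every feature of real data.

`recovery_experiment` tabulates bias, relative bias and RMSE of λ̂ (taken
from the fit matching the generating shape) plus shape-selection
frequencies over seeded simulation grids; per-simulation seeds are spawned
from a master generator and kept below 2³¹.

## Survey summarizer

Study-level records carry organism kind, environmental variable(s), trait
measurements (each with its number of post-shift measurement occasions),
control design and a formal-quantification flag. Statistics: proportions
of trait measurements by category; proportions of studies by environmental
variable (studies manipulating more than one variable are excluded from
this breakdown only, with a logged notice), organism kind and control
design; studies per year; the grand mean of per-study mean measurement
counts (the mean of means, so multi-trait studies are not overweighted);
and the percentage of studies formally quantifying a rate, reported to one
decimal place. Category vocabularies (including the 13
environmental-variable categories) ship as editable defaults and can be
overridden from JSON, since surveys differ in how they slice these.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` use: 200 random series for the
grid-search oracle comparison (10⁵-point log grid on [1e−4, 10]); 500
simulations for exponential recovery (λ = 0.05, noise 0.05) and for
bootstrap coverage (λ = 0.1, noise 0.05, 500 resamples each); 200
simulations for linear shape selection (noise 0.02). These
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands.

## Known limitations

* λ is assumed constant in time; biphasic or time-varying rates are not
  modeled.
* One trait at a time; no multivariate or mixed-effects structure.
* The RSE comparison is the standardized procedure, not a calibrated
  hypothesis test; near-tie margins should be interpreted with the
  bootstrap, not as evidence about the true shape.
* Rates fitted under different shapes are not mutually comparable; compare
  half-times only within a shape.
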