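# Methods

This note documents the statistical model the package implements, the
defaults and why they were chosen, the numerical choices that matter, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Stage 1: community x subperiod exposure-response

Each community's series is cut into calendar 5-year nonoverlapping
subperiods (default window 1986-2015, periods w = 1..6; a restricted
2001-2015 window is a configuration option). Subperiods are treated as
independent series: lagged exposures never borrow days from the previous
subperiod, so the first L = 21 days of each block are excluded from the fit.
This is the conservative reading of a model defined "for t = L+1, ..., N";
the alternative (carrying lags across the boundary) would couple adjacent
subperiods and conflict with the independence the second stage assumes.

For each community x subperiod the daily death count is modelled as
overdispersed Poisson with

* an intercept,
* a natural cubic spline of time with `round(8 * days/365.25)` degrees of
  freedom and equally spaced internal knots (seasonality and long-term
  trend),
* six day-of-week indicators (Monday reference),
* the DLNM cross-basis: temperature spline with three internal knots at the
  10th/75th/90th percentiles of the subperiod's temperatures and boundary
  knots at its min/max (vx = 4, no intercept); lag spline over 0..21 days
  with an intercept and three internal knots equally spaced on the log
  scale, knot_i = exp(i * log(L) / 4) (vl = 5). The cross-basis has
  vx * vl = 20 columns.

Fitting is Fisher-scoring IRLS for the Poisson likelihood; the coefficient
covariance is inflated by the Pearson dispersion chi^2/(n - p)
(quasi-Poisson). The tests verify the fit against statsmodels' GLM and an
independently coded naive IRLS loop to 1e-8.

### Natural cubic splines

The basis is built from a cubic B-spline basis on the augmented knot
sequence with the two non-natural directions (non-zero second derivative at
the boundary knots) projected out via the QR complement of the constraint
matrix, mirroring the `ns` convention of R's splines package, including
dropping the first B-spline column when the basis excludes an intercept.
Beyond the boundary knots evaluation is linear (value plus first derivative
at the boundary). When a basis includes an intercept, the first column is a
literal column of ones and the rest is the intercept-free basis — same
span, cleaner downstream algebra (the lag basis matrix C then has an
all-ones first column). Only the span matters for fitted curves and the
MMT, which is what the truncated-power oracle test checks.

Quantile convention for knot placement: linear interpolation between order
statistics (numpy's default). Knots move the fitted curve, and therefore
the MMT, slightly; fixing the convention makes runs reproducible across
environments.

### MMT and its uncertainty

The 20 cross-basis coefficients are cumulated over lags with the reducing
matrix M1 = I_vx kron (1' C), giving the 4-coefficient lag-cumulative curve
theta with covariance M1 V(beta) M1'. The MMT is the argmin of
sum_k theta_k f_k(x) over a grid in 0.1 degC steps (configurable) covering
the subperiod's 25th-99th percentile temperature window; ties break to the
lowest temperature. The grid search, rather than a continuous optimizer,
makes the argmin deterministic and trivially correct; 0.1 degC is far below
the Monte-Carlo uncertainty of any real fit.

Uncertainty: 1000 draws theta_(s) ~ N(theta_hat, V(theta_hat)), each
re-minimized on the same grid; the sample SD of the 1000 argmins is the
standard error (no CI percentiles are propagated downstream). V(theta) is
projected to the PSD cone by eigenvalue clipping at zero before sampling —
short subperiods can produce numerically indefinite covariances, and the MC
step needs a valid one. The MMTP is 100 x the proportion of the subperiod's
non-missing daily temperatures <= MMT (weak inequality; ties count fully),
and the MMTP standard error is the SD of the 1000 converted MC samples.

Per-unit seeds are derived from the run seed, a CRC of the community id and
the period index, so results are independent of the processing order and
reproducible record by record.

### Usability filter

A community x subperiod is dropped when it has fewer than 2 years of days,
fewer than 500 total deaths, the temperature knots are degenerate, or the
IRLS fails — sparse units produce argmin estimates dominated by boundary
noise. Failures are logged and excluded; they never abort a run.

## Stage 2: two-level mixed-effects meta-regression

Estimates y_ijw with known standard errors sd_ijw are pooled by

    y_ijw = x_ijw' b + z' u_ij + z' v_i + eps_ijw,

with z = (1, time_w)', community effects u_ij ~ N(0, Psi2), country effects
v_i ~ N(0, Psi1) and eps_ijw ~ N(0, sd_ijw^2) fixed (not estimated). MMT
and MMTP are pooled in separate, parallel runs, never jointly.

Estimation profiles the fixed effects out by GLS and maximizes the
(restricted) likelihood over the two covariances, parameterized by their
log-Cholesky factors so every proposal is positive semidefinite. The
likelihood factorizes over countries, so each evaluation solves one small
dense Cholesky system per country. An analytic gradient (envelope theorem
for the profiled fixed effects plus standard trace identities) feeds
L-BFGS-B, started from a small grid of three scale-aware starting values —
the restricted surfaces occasionally have a shallow local optimum, and the
multi-start reliably escapes it. Convergence tolerance 1e-10 (relative) on
the objective.

Flavors: REML for reported fits and for comparisons of random structures;
ML refits for likelihood-ratio tests of fixed effects (interactions, AT
terms), since REML likelihoods with different fixed designs are not
comparable. AIC = -2 ll + 2(p + q) and BIC = -2 ll + log(n) (p + q) with
p fixed and q variance parameters, n the number of records.

BLUPs are the conditional means Psi Z' V^{-1}(y - X b_hat) per country
block; the community-level prediction adds fixed + country + community
parts. Stratified fits (climate zone, region, country) refit the same model
on the stratum's records only.

### Heterogeneity ladder

Four comparisons: climate-zone x time and region x time interactions (ML;
the reduced model keeps the stratum main effects so the test isolates the
interaction, df = levels - 1), and country- and community-level random
slopes (REML; removing a slope removes one variance and one covariance,
df = 2). Likelihood-ratio tests for variance components at the boundary use
the naive chi-square reference with df equal to the number of removed
covariance parameters; this is conservative, and no 50:50 mixture
correction is applied. Per-row failures yield NaN rows rather than aborting
the ladder.

### Average-temperature adjustment

Three fits are reported overall and per stratum: time only, time + AT
(subperiod average temperature), and time + (AT - TAT) (AT centered at its
community time-average). Both AT variants are reported because either
centering is defensible and they answer slightly different questions (raw
AT also absorbs between-community temperature differences; centered AT
isolates within-community warming). A warning with the design condition
number is emitted when AT is nearly collinear with time within a stratum.

## Synthetic data

The generator emulates the structure the analysis assumes:

* **Temperature**: community mean (country means uniform on 6-24 degC,
  community offsets SD 1.5) + annual sinusoid (amplitude 8 degC) + linear
  warming (0.3 degC/decade) + AR(1) noise (rho 0.6, marginal SD 2 degC).
* **Mortality**: negative-binomial counts (variance = phi * mean,
  phi = 1.5) — not Poisson, so the quasi-Poisson stage faces genuine
  overdispersion — with log-rate = baseline (30 deaths/day) + winter-peaked
  seasonality (amplitude 0.10 on the log scale) + day-of-week effects + a
  U-shaped lagged temperature term: an exponential lag decay (half-life 3
  days, normalized over lags 0..21) of a quadratic with curvature 0.004 per
  degC^2 centered at the true MMT. The curvature corresponds to a
  cumulative relative rate of ~1.5 at 10 degC from the MMT, a typical
  magnitude for all-cause temperature-mortality curves.
* **Truth**: the true MMT sits `mmt_offset` (default 6 degC, near the 75th
  percentile) above the community mean and moves as a step function,
  constant within each subperiod and linear in w across subperiods, with
  country- and community-level random intercept/slope deviations matching
  the two-level structure the second stage estimates. The truth table emits
  the exact MMT and MMTP per community x subperiod.

What it does **not** emulate: holidays, influenza epidemics, heat-wave
mortality displacement, demographic change, missing data patterns, or any
deviation of the true curve from the quadratic-with-exponential-lag form.
Passing recovery tests therefore show the estimator chain is correct under
its own assumptions — not that those assumptions hold for real registries.
A separate representability check verifies the generator's log-rate surface
lies within ~2% of the DLNM cross-basis span, so first-stage bias in tests
reflects estimation error, not model misspecification.

A second, much cheaper simulator (`simulate_memr_records`) draws subperiod
records directly from the pooling model with configurable heterogeneity,
region-specific slopes and AT-driven confounding; it exercises the second
stage in isolation (coverage, test calibration, adjustment behavior).

## Problem sizes in tests

The replicated checks run at deliberately modest sizes chosen to keep the
full suite fast while leaving the statistical conclusions stable: slope
recovery uses 20 end-to-end replicates of 10 countries x 5 communities;
the interaction-test calibration uses 200 record-level replicates of 20
countries in 4 regions; the AT-adjustment checks use 30 replicates per
scenario. Binomial tolerances in the assertions match these replicate
counts.

## Known limitations

* The MEMR assumes first-stage errors are independent across subperiods
  within a community; subperiod blocks are refit independently to make this
  hold by construction, at the cost of discarding the first 21 days of each
  block.
* Boundary variance components (Psi entries at zero) make the naive
  chi-square reference for random-slope tests conservative.
* The argmin search is restricted to the 25th-99th (or 1st-99th) percentile
  window; genuinely monotone curves pin the MMT at a window edge, and the
  MC standard error then understates the uncertainty beyond the window.
* Time trends are linear in the period index; no nonlinear trend models.
* Cause-specific or age/sex-stratified mortality and humidity adjustment
  are out of scope.
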