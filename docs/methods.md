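# Methods

## Study design emulated

The pipeline analyses daily step counts around an abrupt stressor with three
calendar anchors: a baseline window (default 2019-10-01 up to the lockdown
date), the lockdown date itself (day 0), and an observation end (default
2020-09-30). The confinement period is the four weeks from day 0; the
recovery period runs from day 28 to the observation end.

## Preprocessing and inclusion

A day is *valid* if wear time is recorded and ≥ 600 minutes with ≥ 1 step,
or — when wear time is unavailable — if ≥ 1 step was recorded. Non-valid
days are recoded to missing before any modelling. Daily values above 40,000
steps are capped at 40,000; capping is idempotent and the cap doubles as the
ceiling of the DC scale range.

Weeks are consecutive 7-day blocks anchored at each period's start date, not
ISO calendar weeks; a trailing block shorter than 7 days is dropped from the
denominator. Baseline/recovery weeks are valid with ≥ 1 valid weekend day
(Saturday/Sunday) and ≥ 2 valid weekdays; confinement weeks with ≥ 3 valid
days of any type. Participants are included when all five criteria hold:
≥ 3 valid baseline weeks; all 4 confinement weeks valid; ≥ 70% valid
recovery weeks; < 20% post-lockdown missingness (counted after validity
recoding, over day 0 through the observation end); and a perturbation of at
least 10% of the baseline median. The perturbation is operationalized as
baseline median − median of the *fitted* trajectory over days 0–29; the
median was chosen over the mean for robustness and symmetry with the
baseline definition. The return-to-baseline day is the first day the fitted
smooth reaches 1.10 × the baseline median (the factor allows for seasonally
higher spring/summer activity); searching the smooth rather than raw values
avoids spurious single-day crossings.

## Trajectory model and rate of change

Post-stressor steps are regressed on day index with a P-spline: a cubic
B-spline basis of dimension k (open uniform knots over the post-stressor
window) with a second-order difference penalty on the coefficients. The
smoothing parameter λ is selected by generalized cross-validation over a
49-point log grid from 1e−4 to 1e8; the basis dimension is selected by RMSE
against observed days over candidates {10, 20}, with the larger k preferred
on ties (to numerical precision). The fit uses observed days only — missing
days are *not* imputed on this path, since the smooth itself provides
estimates there — and predicts on the full daily grid.

The rate of change dy/dt is the analytic derivative of the fitted B-spline
(`BSpline.derivative`), cross-checked in the tests against central finite
differences of the fitted values and against analytic derivatives of known
generating curves. Because a straight line lies in the penalty's null space,
noiseless linear data are reproduced exactly at any λ.

## Kalman imputation (DC input path only)

The DC statistic requires a gap-free, equally spaced series, so the DC input
path imputes missing days with the smoothed state of a structural
time-series model: local linear trend plus a period-7 seasonal term
(capturing the weekday/weekend structure), estimated by maximum likelihood,
falling back to trend-only and then local-level specifications if estimation
fails. Two-sided smoothing is used rather than one-sided filtering because
imputation is retrospective. Imputed values stay real-valued (no rounding)
and are clamped to [0, 40,000]. Preconditions: ≥ 15 observed values with at
least one in each third of the window; leading/trailing gaps longer than 14
days are filled by state extrapolation with a warning.

## Dynamic complexity

DC = F · D on a sliding window of 14 observations ending at day *n* (the
stated window length is taken as the number of observations; width 7 is
supported as a config knob). The scale range is fixed a priori at
[0, 40,000] — the theoretical floor and the outlier cap — rather than each
participant's observed range, so DC is comparable across participants.

F: points of return are the first point, every strict local extremum (a
plateau's last point acts as the return point) and the last point; for each
monotone segment between consecutive return points F accumulates
|value difference| / (number of one-day intervals), normalised by
(x_max − x_min)·(m − 1). D: with ideal spacing d = (x_max − x_min)/(m − 1)
over the sorted window, D = 1 − Σ max(0, (j−i)·d − (y(j) − y(i))) / Σ (j−i)·d
over all sorted pairs i < j. Both statistics are invariant under joint
affine rescaling of values and range; D is order-free while F is
order-sensitive. The rolling implementation uses numba kernels and is tested
for exact agreement with a naive pure-Python per-window transcription of the
definitions.

## Lag identification and the multilevel model

For each lag L in 1..30, the Pearson correlation of DC(t−L) with dy/dt(t) is
computed within participant (pairwise-complete) and averaged across
participants with a simple (unweighted) mean; the selected lag attains the
most negative mean correlation — the hypothesized direction, not the largest
absolute value. Zero-variance participants are dropped from a lag's mean
with a warning.

The analysis table stacks participant-days with a defined lagged DC. DC is
z-scored over all pooled rows and the quadratic term is the square of that
z-score (not separately standardized): only under this convention is the
combined effect at x SD, B_lin·x + B_quad·x², coherent arithmetic. Time is
divided by its pooled SD without centering; baseline steps are standardized
between participants.

The mixed model has fixed effects for time, ldc, ldc² and baseline, a random
intercept and random slopes for time, ldc and ldc² by participant
(statsmodels MixedLM). The final fit uses REML with an unstructured
random-effect covariance, falling back to a diagonal covariance on
non-convergence (flagged in the result); BIC comparisons between the
quadratic and linear-only models use ML on identical rows, with BIC
= −2ℓ + p·log(n) counting fixed effects, covariance parameters and the
residual variance. CIs are Wald (±1.96·SE). ICC is the intercept variance
over intercept-plus-residual variance; marginal and conditional R² follow
the fixed-vs-total variance decomposition with the random-effect
contribution averaged over rows (mean of zᵢ'Σzᵢ). The moderation analysis
adds source dummies and their interactions with ldc and ldc², keeping the
random structure.

## Synthetic cohorts and what they do (not) show

The generator draws baseline levels log-normally (median ≈ 10,000 steps/day,
log-SD 0.30) with a 1.15 weekend multiplier, applies a participant-specific
instantaneous drop at lockdown (mean fraction 0.35, SD 0.10), then a linear
drift with participant-specific mean rate (11 steps/day mean, SD 8 —
matching the typical median recovery pace of active adult cohorts), Gaussian
daily noise (SD 1,500), and MCAR missingness (rate 0.10; optional block mode
for consecutive non-wear). Volatility episodes — runs of 14 days starting
with probability 0.02/day whose noise SD is 4,500 — create genuinely
elevated-DC windows.

When `dc_coupling` is non-zero the drift rate on day t is
rate + jitter(t) + dc_coupling·(DC(t−lag) − 0.01)/0.01, where DC is the
*realized* local DC of the series generated so far and 0.01/0.01 are fixed
standardization constants chosen once from the DC statistic's approximate
mean/SD under the default volatility regime. This makes the true rate of
change exactly affine in lagged DC, so a lag scan on a noise-free cohort
must recover the coupling lag with correlation −1 — the sharpest possible
ground-truth check. The rate jitter is AR(1) (ϕ = 0.9) with SD proportional
to the noise level (0.005 × noise SD), giving the rate realistic day-to-day
variation under noise while vanishing in the noise-free case.

What the generator does **not** emulate: country-specific policy timelines,
device or firmware differences, minute-level wear bouts, seasonality beyond
the weekend effect, non-random (informative) missingness, and non-linear
recovery shapes such as fast-then-plateau trajectories. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
class — abrupt drop, drifting linear recovery, volatility-coupled slowdowns —
not that real cohorts satisfy those assumptions.

A separate harness simulates rows directly from the multilevel model
(independent normal random effects, standard-normal ldc, scaled uncentered
time) for parameter-recovery and coverage checks; those fits use a diagonal
random-effect covariance, matching the generating process.

## Numerical choices and problem sizes

Replicated checks run at 100 participants × 150 days (mixed-model recovery,
100 replicates) and 100 participants × ~200 post-stressor days (lag
recovery under noise SD 500, 100 replicates) — sizes at which coverage and
lag-selection behaviour are stable while a full run stays in the minutes
range on a single core. Degenerate inputs raise typed errors
(`ConfigurationError`, `InsufficientDataError`) rather than propagating
NaNs: all-missing imputation input, < 10 observed days for a growth fit,
empty period windows, single-participant mixed models, single-level
moderators.

## Known limitations

- The DC→rate coupling in the generator is linear in standardized DC; the
  quadratic term of the analysis model is therefore validated on the direct
  model simulator, not on generated cohorts.
- Wald CIs slightly undercover variance-component-heavy designs with few
  participants; coverage checks use 100 participants.
- The lag scan on pipeline output uses the smoothed derivative, which blurs
  the selected lag by a few days relative to the generating lag (visible in
  the README example); exact recovery is asserted against the generator's
  true rate profile.
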