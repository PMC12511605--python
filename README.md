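# stepdc

Early-warning analysis of physical-activity recovery after a major stressor.

When an external shock (for example, a pandemic lockdown) abruptly suppresses
daily step counts, people recover at different and time-varying paces. This
package asks whether *local dynamic complexity* (DC) of the step-count time
series — a critical-fluctuation statistic from complex-systems theory —
predicts upcoming slowdowns in the recovery. It is aimed at researchers
working with consumer-wearable step data (Fitbit, Garmin, …) who want a
tested, reproducible pipeline from raw daily counts to a multilevel model.

## The model

For each participant, the post-stressor trajectory of daily steps *y(t)* is
fitted with a penalized cubic regression spline (basis dimension *k*
compared over {10, 20} by RMSE, smoothing parameter by GCV); the recovery's
**rate of change** is the analytic first derivative dy/dt of the fitted
smooth (positive = recovery, negative = setback).

**Dynamic complexity** is DC = F · D on a 14-day moving window scaled to
[0, 40 000] steps: F measures amplitude-and-frequency of change between
consecutive observations (1 for full-range alternation, 0 for a constant
window) and D measures how evenly the window's sorted values cover the scale
range. Both lie in [0, 1].

A cross-correlation scan over lags 1–30 days finds the lag L at which
DC(t−L) is most negatively correlated with dy/dt(t), and a linear mixed
model quantifies the association:

    dy/dt ~ time + ldc + ldc² + baseline + (1 + time + ldc + ldc² | participant)

with `ldc` the pooled z-score of lagged DC and `time` scaled but not
centered. The combined effect of DC at *x* SD from its mean is
B_lin·x + B_quad·x², reported together with 95% CIs, random-effect SDs, ICC,
marginal/conditional R² and BIC.

Because multi-country wearable datasets cannot be bundled, the package ships
a synthetic-cohort generator with known ground truth (baseline level, drop
fraction, true per-day recovery rate, and an optional lagged DC→rate
coupling), so every stage is testable end to end.

## Worked example

```python
from stepdc import SimulationConfig, generate_cohort, run_pipeline
from stepdc.association import format_model_report

cfg = SimulationConfig(n_participants=50, dc_coupling=-10.0, seed=7)
cohort, truth = generate_cohort(cfg)
result = run_pipeline(cohort, cfg.context, seed=7)
print(result.attrition)
print(f"selected lag: {result.lag}")
print(format_model_report(result.model))
```

prints (abridged):

```
{'input': 50, 'baseline_computable': 50, 'growth_fit': 50, 'included': 48, 'dc_path': 48}
selected lag: 14
Fixed effects (DV = rate of change)
----------------------------------------------------------------
Intercept        10.91 (  9.87) [    -8.43,     30.26]  rand SD    65.78
time             -0.31 (  2.09) [    -4.41,      3.79]  rand SD    13.96
ldc_z            -7.76 (  2.13) [   -11.95,     -3.58]  rand SD    13.24
ldc_z_sq          0.86 (  0.32) [     0.23,      1.48]  rand SD     1.43
baseline_z       -3.10 (  1.37) [    -5.79,     -0.42]
----------------------------------------------------------------
residual SD 53.29 | ICC 0.604 | R2 marg 0.013 | R2 cond 0.131
BIC 104023.1 | n obs 9600 | participants 48 | cov unstructured | converged True
```

48 of 50 simulated participants pass the five inclusion criteria. The
negative `ldc_z` coefficient (−7.76, CI excluding 0) recovers the generated
coupling: days with elevated local DC precede slower recovery. The lag scan
lands near — not exactly at — the generating lag of 11 because the
derivative is estimated from a smoothed trajectory.

The same pipeline runs from a shell:

```
stepdc simulate --out sim --seed 1
stepdc run --config cfg.yaml --out results --seed 1 --lag 11
```

where `cfg.yaml` may point at any long-format cohort CSV
(`participant_id, date, steps, wear_minutes, source, device`), including
exported real study data.

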