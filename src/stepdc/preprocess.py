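"""Validity rules, outlier capping, inclusion criteria and baseline summaries.

Daily validity: when wear-time information is available a day is valid only
with at least 600 minutes (10 h) of wear AND at least one recorded step; when
wear time is unavailable, at least one recorded step suffices. Non-valid days
are recoded as missing downstream. Daily step counts above 40,000 are capped
at 40,000.

Weeks are consecutive 7-day blocks anchored at each study period's start
date. Baseline and recovery weeks are valid with >= 1 valid weekend day and
>= 2 valid weekdays; confinement weeks (the four weeks after lockdown) with
>= 3 valid days regardless of day type, since home confinement removes the
weekday/weekend distinction.

Cohort inclusion requires all five criteria: >= 3 valid baseline weeks; all
4 confinement weeks valid; >= 70% valid recovery weeks; < 20% missing values
post-lockdown (after validity recoding); and a perturbation of >= 10% of the
baseline median over the fitted trajectory's first 30 post-lockdown days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    STEP_CAP,
    WEAR_VALID_MINUTES,
    ConfigurationError,
    InsufficientDataError,
    StepSeries,
    StudyContext,
)
from .trajectory import GrowthFit, perturbation_magnitude

RETURN_FACTOR = 1.10
CONFINEMENT_WEEKS = 4
MIN_BASELINE_WEEKS = 3
RECOVERY_VALID_FRACTION = 0.70
MISSING_MAX_FRACTION = 0.20
PERTURBATION_MIN_FRACTION = 0.10

PERIODS = ("baseline", "confinement", "recovery")


@dataclass
class BaselineSummary:
    """Pre-stressor activity level and the derived return-to-baseline threshold.

    The threshold is 1.10 x the baseline median, allowing for the seasonally
    higher activity volumes of spring/summer relative to fall/winter.
    """

    baseline_median_steps: float
    n_valid_baseline_weeks: int
    return_threshold: float

    def __post_init__(self) -> None:
        expected = RETURN_FACTOR * self.baseline_median_steps
        if not np.isclose(self.return_threshold, expected):
            raise ValueError("return_threshold must equal 1.10 x baseline median")


@dataclass
class InclusionReport:
    participant_id: str
    valid_baseline: bool
    valid_confinement: bool
    valid_recovery: bool
    missing_ok: bool
    perturbed: bool

    @property
    def included(self) -> bool:
        return (
            self.valid_baseline
            and self.valid_confinement
            and self.valid_recovery
            and self.missing_ok
            and self.perturbed
        )

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "valid_baseline": self.valid_baseline,
            "valid_confinement": self.valid_confinement,
            "valid_recovery": self.valid_recovery,
            "missing_ok": self.missing_ok,
            "perturbed": self.perturbed,
            "included": self.included,
        }


def flag_valid_days(series: StepSeries) -> np.ndarray:
    """Boolean validity mask aligned to the series dates."""
    steps = series.steps
    has_step = ~np.isnan(steps) & (steps >= 1)
    if series.wear_minutes is None:
        return has_step
    wear = series.wear_minutes
    wear_known = ~np.isnan(wear)
    valid = np.where(wear_known, wear_known & (wear >= WEAR_VALID_MINUTES) & has_step, has_step)
    return valid.astype(bool)


def cap_outliers(series: StepSeries, cap: float = STEP_CAP) -> StepSeries:
    """Recode step counts above the cap to the cap (idempotent)."""
    out = series.copy()
    out.steps = np.where(np.isnan(out.steps), np.nan, np.minimum(out.steps, cap))
    return out


def recode_invalid_to_missing(series: StepSeries, mask: np.ndarray) -> StepSeries:
    """Set non-valid days to missing; dates are untouched."""
    out = series.copy()
    out.steps = np.where(mask, out.steps, np.nan)
    return out


def _period_bounds(period: str, context: StudyContext) -> tuple[pd.Timestamp, pd.Timestamp]:
    if period == "baseline":
        return context.baseline_start, context.lockdown_date - pd.Timedelta(days=1)
    if period == "confinement":
        return context.lockdown_date, context.lockdown_date + pd.Timedelta(days=27)
    if period == "recovery":
        return context.lockdown_date + pd.Timedelta(days=28), context.observation_end
    raise ConfigurationError(f"unknown period {period!r}; expected one of {PERIODS}")


def summarize_weeks(
    series: StepSeries, mask: np.ndarray, period: str, context: StudyContext
) -> np.ndarray:
    """Per-week validity flags for a study period.

    Weeks are consecutive 7-day blocks from the period start; a trailing
    block shorter than 7 days is dropped. Baseline/recovery weeks need >= 1
    valid weekend day and >= 2 valid weekdays; confinement weeks >= 3 valid
    days of any type.
    """
    start, end = _period_bounds(period, context)
    if end < start:
        raise ConfigurationError(f"empty {period} window: {start.date()}..{end.date()}")
    n_weeks = (int((end - start).days) + 1) // 7
    valid_dates = series.dates[np.asarray(mask, dtype=bool)]
    flags = np.zeros(n_weeks, dtype=bool)
    for w in range(n_weeks):
        w_start = start + pd.Timedelta(days=7 * w)
        w_end = w_start + pd.Timedelta(days=6)
        days = valid_dates[(valid_dates >= w_start) & (valid_dates <= w_end)]
        if period == "confinement":
            flags[w] = len(days) >= 3
        else:
            weekend = int((days.dayofweek >= 5).sum())
            weekday = int((days.dayofweek < 5).sum())
            flags[w] = weekend >= 1 and weekday >= 2
    return flags


def compute_baseline(
    series: StepSeries, mask: np.ndarray, context: StudyContext
) -> BaselineSummary:
    """Median daily steps over valid baseline days, plus the return threshold."""
    start, end = _period_bounds("baseline", context)
    in_baseline = (series.dates >= start) & (series.dates <= end)
    valid = np.asarray(mask, dtype=bool) & in_baseline & ~np.isnan(series.steps)
    if not valid.any():
        raise InsufficientDataError(
            f"participant {series.participant_id}: no valid baseline days"
        )
    median = float(np.median(series.steps[valid]))
    weeks = summarize_weeks(series, mask, "baseline", context)
    return BaselineSummary(
        baseline_median_steps=median,
        n_valid_baseline_weeks=int(weeks.sum()),
        return_threshold=RETURN_FACTOR * median,
    )


def post_lockdown_missing_fraction(
    series: StepSeries, mask: np.ndarray, context: StudyContext
) -> float:
    """Fraction of missing days from lockdown through observation end.

    Computed after validity recoding: invalid days count as missing. Days not
    present in the series at all also count as missing.
    """
    post = (series.dates >= context.lockdown_date) & (series.dates <= context.observation_end)
    n_total = context.n_post_days
    present_valid = np.asarray(mask, dtype=bool) & post & ~np.isnan(series.steps)
    return 1.0 - present_valid.sum() / n_total


def apply_inclusion_criteria(
    series: StepSeries,
    mask: np.ndarray,
    fit: GrowthFit,
    baseline: BaselineSummary,
    context: StudyContext,
) -> InclusionReport:
    """Evaluate the five cohort-inclusion criteria for one participant."""
    baseline_weeks = summarize_weeks(series, mask, "baseline", context)
    confinement_weeks = summarize_weeks(series, mask, "confinement", context)
    recovery_weeks = summarize_weeks(series, mask, "recovery", context)
    missing_frac = post_lockdown_missing_fraction(series, mask, context)
    perturb = perturbation_magnitude(fit, baseline.baseline_median_steps)
    return InclusionReport(
        participant_id=series.participant_id,
        valid_baseline=int(baseline_weeks.sum()) >= MIN_BASELINE_WEEKS,
        valid_confinement=bool(confinement_weeks.all())
        and len(confinement_weeks) == CONFINEMENT_WEEKS,
        valid_recovery=(
            recovery_weeks.mean() >= RECOVERY_VALID_FRACTION if len(recovery_weeks) else False
        ),
        missing_ok=missing_frac < MISSING_MAX_FRACTION,
        perturbed=perturb >= PERTURBATION_MIN_FRACTION * baseline.baseline_median_steps,
    )


def compute_return_day(fit: GrowthFit, baseline: BaselineSummary) -> int | None:
    """First post-stressor day whose fitted value reaches the return threshold.

    Returns days since lockdown, or None if the fitted trajectory never
    reaches 1.10 x the baseline median by the observation end. The fitted
    smooth, not the raw observations, is searched: raw daily noise would
    trigger spurious single-day crossings.
    """
    above = fit.fitted_values >= baseline.return_threshold
    if not above.any():
        return None
    return int(np.argmax(above))


def inclusion_table(reports: list[InclusionReport]) -> pd.DataFrame:
    """One row per participant; convenient CSV export of inclusion flags."""
    return pd.DataFrame([r.to_dict() for r in reports])
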