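"""Kalman-smoother imputation of missing daily step values.

The local-DC statistic requires a gap-free, equally spaced series: missing
days are filled with the smoothed state estimate of a structural time-series
model (local linear trend plus, by default, a period-7 seasonal component
reflecting the weekday/weekend structure of step counts), estimated by
maximum likelihood and smoothed with the Kalman smoother. Smoothing is
two-sided — imputation is retrospective — and observed days are never
altered. Imputed values are real-valued and clamped to the admissible step
scale [0, 40,000].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.structural import UnobservedComponents

from .core import STEP_CAP, InsufficientDataError

MIN_OBSERVED = 15
EDGE_GAP_WARN = 14  # leading/trailing missing runs longer than this draw a warning


@dataclass
class ImputedSeries:
    """Gap-free daily series with provenance flags for imputed positions."""

    dates: pd.DatetimeIndex
    steps: np.ndarray
    imputed_flag: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "steps": self.steps,
                "imputed": self.imputed_flag,
            }
        )


def _check_coverage(y: np.ndarray) -> None:
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs < MIN_OBSERVED:
        raise InsufficientDataError(
            f"Kalman imputation needs >= {MIN_OBSERVED} observed values, got {n_obs}"
        )
    thirds = np.array_split(obs, 3)
    if any(not t.any() for t in thirds):
        raise InsufficientDataError(
            "Kalman imputation needs at least one observation in each third of the window"
        )


def _edge_run_lengths(missing: np.ndarray) -> tuple[int, int]:
    lead = int(np.argmax(~missing)) if missing.any() else 0
    trail = int(np.argmax(~missing[::-1])) if missing.any() else 0
    return lead, trail


def kalman_impute(
    steps,
    dates: pd.DatetimeIndex | None = None,
    seasonal: bool = True,
    edge_gap_warn: int = EDGE_GAP_WARN,
) -> ImputedSeries:
    """Fill NaN entries of a daily step series with Kalman-smoothed estimates.

    A complete series is returned unchanged (identity; all flags False).
    Falls back from trend+seasonal to a local-level specification when the
    richer model fails to converge.
    """
    y = np.asarray(steps, dtype=float)
    if dates is None:
        dates = pd.date_range("2000-01-01", periods=len(y), freq="D")
    dates = pd.DatetimeIndex(dates)
    missing = np.isnan(y)
    if not missing.any():
        return ImputedSeries(dates=dates, steps=y.copy(), imputed_flag=missing.copy())
    _check_coverage(y)

    lead, trail = _edge_run_lengths(missing)
    if max(lead, trail) > edge_gap_warn:
        warnings.warn(
            f"leading/trailing missing run of {max(lead, trail)} days exceeds "
            f"{edge_gap_warn}; filled by state extrapolation",
            stacklevel=2,
        )

    specs = [dict(level="local linear trend", seasonal=7)] if seasonal else []
    specs += [dict(level="local linear trend"), dict(level="local level")]
    smoothed = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for spec in specs:
            try:
                model = UnobservedComponents(y, **spec)
                res = model.fit(disp=False, method="lbfgs", maxiter=200)
                smoothed = np.asarray(res.smoother_results.smoothed_forecasts).ravel()
                if np.isfinite(smoothed[missing]).all():
                    break
                smoothed = None
            except Exception:
                smoothed = None
    if smoothed is None:
        raise InsufficientDataError("state-space imputation failed to produce estimates")

    out = y.copy()
    out[missing] = np.clip(smoothed[missing], 0.0, STEP_CAP)
    return ImputedSeries(dates=dates, steps=out, imputed_flag=missing)
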