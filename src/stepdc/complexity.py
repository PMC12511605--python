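"""Dynamic complexity (DC) of a step-count time series.

DC is an early-warning statistic for instability: the product of a
fluctuation measure F (order-sensitive; amplitude and frequency of change)
and a distribution parameter D (order-free; evenness with which the window's
values cover the scale range). Both lie in [0, 1], so DC does too. "Local"
DC is DC computed on a fixed-width moving window (default 14 days) and
assigned to the window's final day.

F walks the window's points of return — the first point, every strict local
extremum (plateaus contribute their last point) and the last point — and for
each monotone segment between consecutive return points accumulates
|value difference| / (number of one-day intervals); the total is normalised
by the maximal attainable fluctuation (x_max − x_min)·(m − 1). Full-range
alternation therefore attains F = 1 and a constant window F = 0.

D sorts the window and compares empirical order-statistic differences with
the ideal equispaced coverage of the scale range: with ideal spacing
d = (x_max − x_min)/(m − 1), D = 1 − Σ max(0, (j−i)·d − (y(j) − y(i))) /
Σ (j−i)·d over all sorted index pairs i < j. A window whose sorted values
are equispaced across the full range attains D = 1; a constant window D = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core import STEP_CAP


@dataclass(frozen=True)
class ScaleRange:
    """A priori range of possible values on the measurement scale."""

    x_min: float = 0.0
    x_max: float = float(STEP_CAP)

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")

    @property
    def span(self) -> float:
        return self.x_max - self.x_min


@dataclass
class ComplexitySeries:
    """Per-day F, D and DC aligned to each moving window's last day.

    The first ``width − 1`` positions are NaN (no complete window ends there).
    """

    dates: pd.DatetimeIndex
    fluctuation: np.ndarray
    distribution: np.ndarray
    dc: np.ndarray
    width: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "F": self.fluctuation,
                "D": self.distribution,
                "DC": self.dc,
            }
        )


def _check_window(values: np.ndarray, rng: ScaleRange) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("window must be 1-D with at least two values")
    if np.isnan(values).any():
        raise ValueError("window contains missing values; impute first")
    if values.min() < rng.x_min or values.max() > rng.x_max:
        raise ValueError("values outside the scale range; cap/clamp first")
    return values


@njit(cache=True)
def _fluct_kernel(y: np.ndarray, span: float) -> float:
    m = y.shape[0]
    total = 0.0
    start = 0
    direction = 0  # sign of the segment's movement; 0 while flat
    for i in range(1, m):
        d = y[i] - y[i - 1]
        s = 0
        if d > 0.0:
            s = 1
        elif d < 0.0:
            s = -1
        if s != 0 and direction != 0 and s != direction:
            # reversal: previous point closes the monotone segment
            # (last point of a plateau, when the reversal follows one)
            total += abs(y[i - 1] - y[start]) / (i - 1 - start)
            start = i - 1
            direction = s
        elif s != 0:
            direction = s
    if m - 1 > start:
        total += abs(y[m - 1] - y[start]) / (m - 1 - start)
    return total / (span * (m - 1))


@njit(cache=True)
def _dist_kernel(y_sorted: np.ndarray, span: float) -> float:
    m = y_sorted.shape[0]
    d = span / (m - 1)
    dev = 0.0
    ideal = 0.0
    for i in range(m - 1):
        for j in range(i + 1, m):
            ide = (j - i) * d
            gap = ide - (y_sorted[j] - y_sorted[i])
            if gap > 0.0:
                dev += gap
            ideal += ide
    return 1.0 - dev / ideal


@njit(cache=True)
def _rolling_kernel(values: np.ndarray, width: int, span: float) -> tuple:
    n = values.shape[0]
    f = np.full(n, np.nan)
    dd = np.full(n, np.nan)
    for end in range(width - 1, n):
        w = values[end - width + 1 : end + 1]
        f[end] = _fluct_kernel(w, span)
        dd[end] = _dist_kernel(np.sort(w), span)
    return f, dd


def fluctuation_intensity(window, scale_range: ScaleRange = ScaleRange()) -> float:
    """Fluctuation measure F in [0, 1] of one window of ordered values."""
    y = _check_window(np.asarray(window, dtype=float), scale_range)
    return float(_fluct_kernel(y, scale_range.span))


def distribution_parameter(window, scale_range: ScaleRange = ScaleRange()) -> float:
    """Distribution parameter D in [0, 1] of one window of values (order-free)."""
    y = _check_window(np.asarray(window, dtype=float), scale_range)
    return float(_dist_kernel(np.sort(y), scale_range.span))


def dynamic_complexity(window, scale_range: ScaleRange = ScaleRange()) -> float:
    """DC = F · D for one window."""
    y = _check_window(np.asarray(window, dtype=float), scale_range)
    return float(_fluct_kernel(y, scale_range.span) * _dist_kernel(np.sort(y), scale_range.span))


def rolling_dc(
    values,
    dates: pd.DatetimeIndex | None = None,
    width: int = 14,
    scale_range: ScaleRange = ScaleRange(),
) -> ComplexitySeries:
    """Local DC over a gap-free daily series.

    The DC at day *n* is computed from the ``width`` consecutive values
    ending at day *n*; the first ``width − 1`` days are NaN. The input must
    be equally spaced with no missing values (impute first): the distribution
    parameter is meaningless on unequally spaced observations.
    """
    values = np.asarray(values, dtype=float)
    if width < 2:
        raise ValueError("window width must be at least 2")
    if len(values) < width:
        raise ValueError("series shorter than the window width")
    if np.isnan(values).any():
        raise ValueError("series contains missing values; impute first")
    if values.min() < scale_range.x_min or values.max() > scale_range.x_max:
        raise ValueError("values outside the scale range; cap/clamp first")
    f, d = _rolling_kernel(values, width, scale_range.span)
    if dates is None:
        dates = pd.date_range("2000-01-01", periods=len(values), freq="D")
    return ComplexitySeries(
        dates=pd.DatetimeIndex(dates),
        fluctuation=f,
        distribution=d,
        dc=f * d,
        width=width,
    )
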