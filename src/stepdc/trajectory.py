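"""Smooth growth model of the post-stressor step trajectory.

The recovery trajectory is modelled as a penalized cubic B-spline regression
of daily steps on day index (a P-spline: B-spline basis with a second-order
difference penalty on the coefficients, smoothing parameter chosen by
generalized cross-validation). The rate of change dy/dt of the recovery —
positive when the participant is regaining steps, negative during a setback,
zero at a stationary point — is the analytic first derivative of the fitted
spline. Candidate basis dimensions are compared by RMSE against the observed
days and the best fit retained (the larger k wins ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .core import InsufficientDataError

DEFAULT_K_CANDIDATES = (10, 20)
_DEGREE = 3  # cubic


@dataclass
class GrowthFit:
    """A fitted smooth trajectory over days 0..T since the stressor."""

    k: int
    lam: float
    days: np.ndarray                # full daily grid, 0..T
    fitted_values: np.ndarray       # one per day in `days`
    derivative: np.ndarray          # dy/dt, steps/day, one per day
    rmse: float                     # on observed (non-imputed) days only
    effective_dof: float
    spline: BSpline = field(repr=False)
    derivative_ci: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self, observed_days=None, observed=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"day_index": self.days, "fitted": self.fitted_values, "derivative": self.derivative}
        )
        if observed_days is not None:
            obs = pd.Series(np.asarray(observed, dtype=float), index=np.asarray(observed_days))
            df["observed"] = df["day_index"].map(obs)
        return df


def _bspline_design(x: np.ndarray, k: int, x_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of a cubic B-spline basis with k functions on [0, x_max]."""
    n_interior = k - _DEGREE - 1
    if n_interior < 0:
        raise ValueError(f"k={k} too small for cubic splines (need k >= {_DEGREE + 1})")
    interior = np.linspace(0.0, x_max, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.zeros(_DEGREE + 1), interior, np.full(_DEGREE + 1, x_max)]
    )
    design = BSpline.design_matrix(np.clip(x, 0.0, x_max), knots, _DEGREE).toarray()
    return design, knots


def _fit_pspline(
    x: np.ndarray, y: np.ndarray, k: int, x_max: float, lambdas: np.ndarray | None = None
) -> tuple[BSpline, float, float]:
    """Penalized least-squares spline fit with GCV-selected smoothing parameter.

    Returns (fitted BSpline, selected lambda, effective dof).
    """
    B, knots = _bspline_design(x, k, x_max)
    n = len(y)
    D = np.diff(np.eye(k), n=2, axis=0)      # second-order difference penalty
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    if lambdas is None:
        lambdas = np.logspace(-4, 8, 49)
    best = (np.inf, None, None, None)
    for lam in lambdas:
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
            # tr(H) = tr((B'B + λP)^{-1} B'B)
            edof = float(np.trace(np.linalg.solve(A, BtB)))
        except np.linalg.LinAlgError:
            continue
        resid = y - B @ coef
        rss = float(resid @ resid)
        denom = max(n - edof, 1e-8)
        gcv = n * rss / denom**2
        if gcv < best[0]:
            best = (gcv, lam, coef, edof)
    if best[1] is None:
        raise np.linalg.LinAlgError("penalized spline fit failed at every lambda")
    _, lam, coef, edof = best
    return BSpline(knots, coef, _DEGREE, extrapolate=True), float(lam), edof


def fit_growth(
    observed_days,
    observed_steps,
    n_days: int | None = None,
    k_candidates=DEFAULT_K_CANDIDATES,
) -> GrowthFit:
    """Fit candidate smooths to post-stressor observed days; keep the lowest-RMSE one.

    Parameters
    ----------
    observed_days : day indices (0 = stressor day) of the observed values.
    observed_steps : observed daily steps (no NaN).
    n_days : length of the full daily grid to predict on (default: last
        observed day + 1).
    k_candidates : basis dimensions to compare; ties go to the larger k.
    """
    x = np.asarray(observed_days, dtype=float)
    y = np.asarray(observed_steps, dtype=float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        x, y = x[keep], y[keep]
    if len(y) < 10:
        raise InsufficientDataError(
            f"growth model needs >= 10 observed days, got {len(y)}"
        )
    if n_days is None:
        n_days = int(x.max()) + 1
    ks = sorted(set(int(k) for k in k_candidates))
    usable = [k for k in ks if len(y) >= k + 1]
    if not usable:
        usable = [max(_DEGREE + 1, len(y) - 1)]
        warnings.warn(
            f"too few observations for requested basis dimensions {ks}; using k={usable[0]}",
            stacklevel=2,
        )
    elif len(usable) < len(ks):
        warnings.warn(
            f"dropping basis dimensions {sorted(set(ks) - set(usable))}: too few observations",
            stacklevel=2,
        )

    grid = np.arange(n_days, dtype=float)
    x_max = float(max(x.max(), n_days - 1))
    best: GrowthFit | None = None
    for k in usable:  # ascending: >= keeps the larger k on ties
        spline, lam, edof = _fit_pspline(x, y, k, x_max)
        rmse = float(np.sqrt(np.mean((y - spline(x)) ** 2)))
        # ties (to numerical precision) go to the larger k
        if best is None or rmse <= best.rmse + 1e-9 * max(1.0, best.rmse):
            best = GrowthFit(
                k=k,
                lam=lam,
                days=grid.astype(int),
                fitted_values=spline(grid),
                derivative=spline.derivative()(grid),
                rmse=rmse,
                effective_dof=edof,
                spline=spline,
            )
    assert best is not None
    return best


def rate_of_change(fit: GrowthFit) -> np.ndarray:
    """Per-day dy/dt of the fitted smooth (positive = recovery, negative = setback)."""
    return fit.derivative


def perturbation_magnitude(fit: GrowthFit, baseline_median: float) -> float:
    """Drop in daily steps over the 30 days after the stressor.

    baseline median − median(fitted values over post-stressor days 0–29);
    negative when the trajectory sits above baseline (no perturbation).
    """
    if len(fit.fitted_values) < 30:
        raise InsufficientDataError("fit must cover post-stressor days 0-29")
    return float(baseline_median - np.median(fit.fitted_values[:30]))
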