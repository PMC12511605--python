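"""Lag identification and the multilevel model of DC on the rate of change.

The predictive lag is found by a cross-correlation scan: for each lag L in
1..30, the Pearson correlation of local DC at day t−L with the rate of
change at day t is computed within participant and averaged across
participants; the selected lag is the one with the most negative mean
correlation (the hypothesized direction: elevated complexity precedes
slowdowns).

At the selected lag a linear mixed model is fitted to the stacked
participant-day table:

    rate_of_change ~ time + ldc_z + ldc_z^2 + baseline_z
                     + (1 + time + ldc_z + ldc_z^2 | participant)

with ldc_z the pooled z-score of the lagged local DC (its quadratic term is
the square of the z-score, so the combined effect at x SD above the mean is
B_lin*x + B_quad*x^2), time scaled by its pooled SD but not centered, and
baseline steps standardized between participants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .core import ConfigurationError, InsufficientDataError

logger = logging.getLogger(__name__)

MAX_LAG = 30
FIXED_TERMS = ("Intercept", "time", "ldc_z", "ldc_z_sq", "baseline_z")


@dataclass
class CrossCorrResult:
    lags: np.ndarray
    mean_correlation: np.ndarray          # per lag, averaged across participants
    selected_lag: int
    per_participant: dict                 # participant -> correlation at selected lag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "mean_correlation": self.mean_correlation})


@dataclass
class MixedModelFit:
    fixed_effects: pd.DataFrame           # estimate, se, ci_low, ci_high per term
    random_sd: dict                       # term -> random-effect SD
    residual_sd: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    bic: float
    n_obs: int
    n_participants: int
    converged: bool
    covariance_structure: str             # "unstructured" | "diagonal"
    result: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects.to_dict(orient="index"),
            "random_sd": self.random_sd,
            "residual_sd": self.residual_sd,
            "icc": self.icc,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "converged": self.converged,
            "covariance_structure": self.covariance_structure,
        }


@dataclass(frozen=True)
class CombinedEffect:
    """B_lin*x + B_quad*x^2 at x SD of DC, in rate-of-change units."""

    x: float
    value: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok], b[ok]
    if a.std() == 0.0 or b.std() == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def lag_scan(
    dc_by_participant: dict,
    roc_by_participant: dict,
    max_lag: int = MAX_LAG,
) -> CrossCorrResult:
    """Mean cross-correlation of DC(t−L) with rate_of_change(t) for L = 1..max_lag.

    Each participant's two arrays must share the same daily alignment (index
    0 = the same calendar day); NaNs (undefined DC, pre-stressor days) are
    dropped pairwise. Participants with zero variance at a lag are dropped
    from that lag's mean with a warning.
    """
    pids = [p for p in dc_by_participant if p in roc_by_participant]
    if len(pids) < 2:
        raise InsufficientDataError("lag scan needs at least two participants")
    lags = np.arange(1, max_lag + 1)
    corr = np.full((len(pids), max_lag), np.nan)
    for i, pid in enumerate(pids):
        dc = np.asarray(dc_by_participant[pid], dtype=float)
        roc = np.asarray(roc_by_participant[pid], dtype=float)
        if len(dc) != len(roc):
            raise ValueError(f"{pid}: DC and rate series are not aligned")
        for j, L in enumerate(lags):
            corr[i, j] = _pearson(dc[:-L], roc[L:])
    dropped = [pids[i] for i in range(len(pids)) if np.isnan(corr[i]).all()]
    if dropped:
        logger.warning("lag scan dropped zero-variance participants: %s", dropped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_corr = np.nanmean(corr, axis=0)
    selected = int(lags[np.nanargmin(mean_corr)])
    return CrossCorrResult(
        lags=lags,
        mean_correlation=mean_corr,
        selected_lag=selected,
        per_participant={pid: corr[i, selected - 1] for i, pid in enumerate(pids)},
    )


def build_long_table(
    dc_by_participant: dict,
    roc_by_participant: dict,
    baseline_by_participant: dict,
    lag: int,
    source_by_participant: dict | None = None,
) -> pd.DataFrame:
    """Stacked participant-day rows with lagged, standardized local DC.

    One row per day t with both rate_of_change(t) and DC(t−lag) defined.
    ldc_z is z-scored over all pooled rows and ldc_z_sq is its square; time
    (days since the first row's day within each participant alignment) is
    divided by its pooled SD without centering; baseline steps are z-scored
    across participants.
    """
    if lag < 1:
        raise ConfigurationError("lag must be >= 1")
    rows = []
    for pid, roc in roc_by_participant.items():
        dc = np.asarray(dc_by_participant[pid], dtype=float)
        roc = np.asarray(roc, dtype=float)
        t = np.arange(len(roc))
        ldc = np.full(len(roc), np.nan)
        ldc[lag:] = dc[:-lag]
        ok = ~np.isnan(ldc) & ~np.isnan(roc)
        if not ok.any():
            continue
        rows.append(pd.DataFrame({
            "participant_id": pid,
            "day": t[ok],
            "rate_of_change": roc[ok],
            "ldc_raw": ldc[ok],
            "baseline_steps": baseline_by_participant[pid],
            "source": (source_by_participant or {}).get(pid, "unknown"),
        }))
    if not rows:
        raise InsufficientDataError("no rows with defined lagged DC")
    df = pd.concat(rows, ignore_index=True)
    ldc_sd = df["ldc_raw"].std(ddof=0)
    if ldc_sd == 0:
        raise InsufficientDataError("lagged DC has zero pooled variance")
    df["ldc_z"] = (df["ldc_raw"] - df["ldc_raw"].mean()) / ldc_sd
    df["ldc_z_sq"] = df["ldc_z"] ** 2
    df["time"] = df["day"] / df["day"].std(ddof=0)
    b = df.groupby("participant_id")["baseline_steps"].first()
    b_sd = b.std(ddof=0)
    bz = (b - b.mean()) / (b_sd if b_sd > 0 else 1.0)
    df["baseline_z"] = df["participant_id"].map(bz)
    return df


def _bic(result, n_params: int) -> float:
    return float(-2.0 * result.llf + n_params * np.log(result.nobs))


def _fit_mixedlm(
    table: pd.DataFrame,
    fe_cols: list,
    re_cols: list,
    reml: bool,
    diagonal: bool,
) -> tuple:
    endog = table["rate_of_change"].to_numpy()
    exog = sm.add_constant(table[fe_cols].to_numpy())
    exog_re = sm.add_constant(table[re_cols].to_numpy())
    model = MixedLM(endog, exog, groups=table["participant_id"].to_numpy(), exog_re=exog_re)
    free = None
    if diagonal:
        free = MixedLMParams.from_components(
            fe_params=np.ones(exog.shape[1]), cov_re=np.eye(exog_re.shape[1])
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, free=free, method="lbfgs", maxiter=500)
    return model, result


def fit_multilevel(
    table: pd.DataFrame,
    reml: bool = True,
    diagonal: bool = False,
    quadratic: bool = True,
) -> MixedModelFit:
    """Mixed model with random intercept and slopes for time, ldc_z, ldc_z_sq.

    Falls back to a diagonal random-effect covariance if the unstructured fit
    does not converge (flagged in the returned convergence status).
    """
    n_part = table["participant_id"].nunique()
    if n_part < 2:
        raise InsufficientDataError("random effects need at least two participants")
    fe_cols = ["time", "ldc_z"] + (["ldc_z_sq"] if quadratic else []) + ["baseline_z"]
    re_cols = ["time", "ldc_z"] + (["ldc_z_sq"] if quadratic else [])
    structure = "diagonal" if diagonal else "unstructured"
    model, result = _fit_mixedlm(table, fe_cols, re_cols, reml, diagonal)
    if not result.converged and not diagonal:
        logger.warning("unstructured covariance did not converge; refitting diagonal")
        structure = "diagonal"
        model, result = _fit_mixedlm(table, fe_cols, re_cols, reml, diagonal=True)

    names = ["Intercept"] + fe_cols
    fe = pd.DataFrame(
        {
            "estimate": result.fe_params,
            "se": result.bse_fe,
        },
        index=names,
    )
    fe["ci_low"] = fe["estimate"] - 1.96 * fe["se"]
    fe["ci_high"] = fe["estimate"] + 1.96 * fe["se"]

    scale = float(result.scale)
    cov_re = np.asarray(result.cov_re) * 1.0
    re_names = ["Intercept"] + re_cols
    random_sd = {nm: float(np.sqrt(max(cov_re[i, i], 0.0))) for i, nm in enumerate(re_names)}
    icc = float(cov_re[0, 0] / (cov_re[0, 0] + scale))

    # Nakagawa-style decomposition; random-effect variance averaged over rows
    exog = sm.add_constant(table[fe_cols].to_numpy())
    exog_re = sm.add_constant(table[re_cols].to_numpy())
    var_f = float(np.var(exog @ result.fe_params))
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", exog_re, cov_re, exog_re)))
    total = var_f + var_r + scale
    n_params = len(result.params) + 1  # fixed + packed covariance + residual scale

    return MixedModelFit(
        fixed_effects=fe,
        random_sd=random_sd,
        residual_sd=float(np.sqrt(scale)),
        icc=icc,
        r2_marginal=var_f / total,
        r2_conditional=(var_f + var_r) / total,
        bic=_bic(result, n_params),
        n_obs=int(result.nobs),
        n_participants=int(n_part),
        converged=bool(result.converged),
        covariance_structure=structure,
        result=result,
    )


def compare_bic(table: pd.DataFrame, diagonal: bool = False) -> tuple[float, float]:
    """BIC of the model with vs without the quadratic DC term (fixed + random).

    Both models are estimated by maximum likelihood on identical rows.
    """
    with_q = fit_multilevel(table, reml=False, diagonal=diagonal, quadratic=True)
    without_q = fit_multilevel(table, reml=False, diagonal=diagonal, quadratic=False)
    assert with_q.n_obs == without_q.n_obs
    return with_q.bic, without_q.bic


def combined_effect(b_lin: float, b_quad: float, x: float) -> CombinedEffect:
    """Overall DC effect at x SD from the mean: B_lin*x + B_quad*x^2."""
    if not (np.isfinite(b_lin) and np.isfinite(b_quad) and np.isfinite(x)):
        raise ValueError("combined_effect requires finite inputs")
    return CombinedEffect(x=float(x), value=float(b_lin * x + b_quad * x * x))


def cumulative_effect(n_days: int, effect: CombinedEffect) -> float:
    """Cumulative steps delayed/gained over n_days at a constant combined effect."""
    if n_days < 0:
        raise ValueError("n_days must be non-negative")
    return float(n_days * effect.value)


def moderation_analysis(
    table: pd.DataFrame, moderator: str = "source", reml: bool = True, diagonal: bool = False
) -> MixedModelFit:
    """Add moderator dummies and their interactions with ldc_z and ldc_z_sq.

    The random-effect structure is unchanged; the reference level is the
    moderator's first level in sorted order.
    """
    levels = sorted(table[moderator].astype(str).unique())
    if len(levels) < 2:
        raise ConfigurationError(f"moderator {moderator!r} needs >= 2 levels")
    df = table.copy()
    inter_cols = []
    for lv in levels[1:]:
        d = (df[moderator].astype(str) == lv).astype(float)
        df[f"mod_{lv}"] = d
        df[f"mod_{lv}_x_ldc"] = d * df["ldc_z"]
        df[f"mod_{lv}_x_ldc_sq"] = d * df["ldc_z_sq"]
        inter_cols += [f"mod_{lv}", f"mod_{lv}_x_ldc", f"mod_{lv}_x_ldc_sq"]

    n_part = df["participant_id"].nunique()
    if n_part < 2:
        raise InsufficientDataError("random effects need at least two participants")
    fe_cols = ["time", "ldc_z", "ldc_z_sq", "baseline_z"] + inter_cols
    re_cols = ["time", "ldc_z", "ldc_z_sq"]
    structure = "diagonal" if diagonal else "unstructured"
    model, result = _fit_mixedlm(df, fe_cols, re_cols, reml, diagonal)
    if not result.converged and not diagonal:
        structure = "diagonal"
        model, result = _fit_mixedlm(df, fe_cols, re_cols, reml, diagonal=True)

    names = ["Intercept"] + fe_cols
    fe = pd.DataFrame({"estimate": result.fe_params, "se": result.bse_fe}, index=names)
    fe["ci_low"] = fe["estimate"] - 1.96 * fe["se"]
    fe["ci_high"] = fe["estimate"] + 1.96 * fe["se"]
    scale = float(result.scale)
    cov_re = np.asarray(result.cov_re) * 1.0
    re_names = ["Intercept"] + re_cols
    exog = sm.add_constant(df[fe_cols].to_numpy())
    exog_re = sm.add_constant(df[re_cols].to_numpy())
    var_f = float(np.var(exog @ result.fe_params))
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", exog_re, cov_re, exog_re)))
    total = var_f + var_r + scale
    return MixedModelFit(
        fixed_effects=fe,
        random_sd={nm: float(np.sqrt(max(cov_re[i, i], 0.0))) for i, nm in enumerate(re_names)},
        residual_sd=float(np.sqrt(scale)),
        icc=float(cov_re[0, 0] / (cov_re[0, 0] + scale)),
        r2_marginal=var_f / total,
        r2_conditional=(var_f + var_r) / total,
        bic=_bic(result, len(result.params) + 1),
        n_obs=int(result.nobs),
        n_participants=int(n_part),
        converged=bool(result.converged),
        covariance_structure=structure,
        result=result,
    )


def format_model_report(fit: MixedModelFit) -> str:
    """Human-readable fixed/random effect table."""
    lines = ["Fixed effects (DV = rate of change)", "-" * 64]
    for name, row in fit.fixed_effects.iterrows():
        sd = fit.random_sd.get(name, None)
        sd_txt = f"  rand SD {sd:8.2f}" if sd is not None else ""
        lines.append(
            f"{name:<12} {row.estimate:9.2f} ({row.se:6.2f}) "
            f"[{row.ci_low:9.2f}, {row.ci_high:9.2f}]{sd_txt}"
        )
    lines += [
        "-" * 64,
        f"residual SD {fit.residual_sd:.2f} | ICC {fit.icc:.3f} | "
        f"R2 marg {fit.r2_marginal:.3f} | R2 cond {fit.r2_conditional:.3f}",
        f"BIC {fit.bic:.1f} | n obs {fit.n_obs} | participants {fit.n_participants} | "
        f"cov {fit.covariance_structure} | converged {fit.converged}",
    ]
    return "\n".join(lines)
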