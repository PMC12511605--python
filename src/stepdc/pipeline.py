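"""End-to-end orchestration: cohort -> inclusion -> trajectories -> DC -> model.

Stages, mirroring the analysis plan:

1. validity flagging, outlier capping, invalid-day recoding
2. baseline summaries and growth-model fits (observed days only)
3. five-criterion inclusion filtering
4. Kalman imputation (DC input path only) and rolling local DC
5. cross-correlation lag scan (or a fixed lag override)
6. long-table assembly and the multilevel model

The result bundle carries every intermediate artifact plus a manifest with
the seed and configuration hash, so a rerun with the same inputs is
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, complexity, impute, preprocess, trajectory
from .core import InsufficientDataError, StepSeries, StudyContext
from .preprocess import BaselineSummary, InclusionReport
from .trajectory import GrowthFit

logger = logging.getLogger(__name__)


@dataclass
class ParticipantResult:
    series: StepSeries
    baseline: BaselineSummary
    fit: GrowthFit
    report: InclusionReport
    dc: complexity.ComplexitySeries | None = None
    return_day: int | None = None


@dataclass
class PipelineResult:
    context: StudyContext
    participants: dict
    included_ids: list
    lag_result: association.CrossCorrResult | None
    lag: int
    table: pd.DataFrame
    model: association.MixedModelFit
    attrition: dict
    manifest: dict = field(default_factory=dict)


def _participant_stage(
    series: StepSeries, context: StudyContext, k_candidates, skip_imputation: bool,
    dc_window: int, scale_range: complexity.ScaleRange,
) -> ParticipantResult | None:
    mask = preprocess.flag_valid_days(series)
    capped = preprocess.cap_outliers(series)
    clean = preprocess.recode_invalid_to_missing(capped, mask)
    try:
        baseline = preprocess.compute_baseline(clean, mask, context)
    except InsufficientDataError:
        logger.warning("%s: no valid baseline days; excluded", series.participant_id)
        return None
    post = (clean.dates >= context.lockdown_date) & (clean.dates <= context.observation_end)
    post_days = context.post_day_index(clean.dates[post])
    post_steps = clean.steps[post]
    obs = ~np.isnan(post_steps)
    try:
        fit = trajectory.fit_growth(
            post_days[obs], post_steps[obs], n_days=context.n_post_days,
            k_candidates=k_candidates,
        )
    except InsufficientDataError:
        logger.warning("%s: too few post-lockdown days for a growth fit; excluded",
                       series.participant_id)
        return None
    report = preprocess.apply_inclusion_criteria(clean, mask, fit, baseline, context)
    result = ParticipantResult(
        series=clean, baseline=baseline, fit=fit, report=report,
        return_day=preprocess.compute_return_day(fit, baseline),
    )
    if not report.included:
        return result
    if skip_imputation:
        if np.isnan(clean.steps).any():
            logger.info("%s: dropped from DC path (incomplete, imputation skipped)",
                        series.participant_id)
            return result
        imputed_steps = clean.steps
    else:
        imputed = impute.kalman_impute(clean.steps, clean.dates)
        imputed_steps = imputed.steps
    result.dc = complexity.rolling_dc(
        imputed_steps, dates=clean.dates, width=dc_window, scale_range=scale_range
    )
    return result


def run_pipeline(
    cohort: list[StepSeries],
    context: StudyContext,
    seed: int = 0,
    lag: int | None = None,
    dc_window: int = 14,
    scale_range: complexity.ScaleRange = complexity.ScaleRange(),
    k_candidates=trajectory.DEFAULT_K_CANDIDATES,
    skip_imputation: bool = False,
    max_lag: int = association.MAX_LAG,
    reml: bool = True,
    diagonal: bool = False,
) -> PipelineResult:
    """Run the full stressor-response analysis on a cohort.

    With ``skip_imputation`` (complete-case sensitivity mode) participants
    with any post-lockdown missingness are dropped from the DC/model path
    rather than imputed.
    """
    participants: dict[str, ParticipantResult] = {}
    attrition = {"input": len(cohort), "baseline_computable": 0, "growth_fit": 0,
                 "included": 0, "dc_path": 0}
    for series in cohort:
        res = _participant_stage(series, context, k_candidates, skip_imputation,
                                 dc_window, scale_range)
        if res is None:
            continue
        attrition["baseline_computable"] += 1
        attrition["growth_fit"] += 1
        participants[series.participant_id] = res
        if res.report.included:
            attrition["included"] += 1
            if res.dc is not None:
                attrition["dc_path"] += 1
    logger.info("attrition: %s", attrition)

    analysed = {pid: r for pid, r in participants.items()
                if r.report.included and r.dc is not None}
    if len(analysed) < 2:
        raise InsufficientDataError("fewer than two participants survive the filters")

    dc_map, roc_map, base_map, src_map = {}, {}, {}, {}
    for pid, r in analysed.items():
        n_total = len(r.series)
        roc = np.full(n_total, np.nan)
        start = int((context.lockdown_date - r.series.dates[0]).days)
        roc[start : start + len(r.fit.derivative)] = r.fit.derivative
        dc_map[pid] = r.dc.dc
        roc_map[pid] = roc
        base_map[pid] = r.baseline.baseline_median_steps
        src_map[pid] = r.series.source

    lag_result = None
    if lag is None:
        lag_result = association.lag_scan(dc_map, roc_map, max_lag=max_lag)
        lag = lag_result.selected_lag
    table = association.build_long_table(dc_map, roc_map, base_map, lag, src_map)
    model = association.fit_multilevel(table, reml=reml, diagonal=diagonal)

    manifest = {
        "seed": seed,
        "lag": lag,
        "dc_window": dc_window,
        "n_input": len(cohort),
        "n_included": attrition["included"],
        "config_hash": hashlib.sha256(
            json.dumps(
                {"seed": seed, "lag": lag, "dc_window": dc_window,
                 "skip_imputation": skip_imputation, "k": list(k_candidates)},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    return PipelineResult(
        context=context, participants=participants,
        included_ids=sorted(analysed), lag_result=lag_result, lag=lag,
        table=table, model=model, attrition=attrition, manifest=manifest,
    )


def write_bundle(result: PipelineResult, out_dir) -> None:
    """Write the inclusion report, per-participant CSVs, lag table and model report."""
    out = Path(out_dir)
    (out / "participants").mkdir(parents=True, exist_ok=True)
    preprocess.inclusion_table(
        [r.report for r in result.participants.values()]
    ).to_csv(out / "inclusion_report.csv", index=False)
    for pid, r in result.participants.items():
        if not r.report.included:
            continue
        post = (r.series.dates >= result.context.lockdown_date) & (
            r.series.dates <= result.context.observation_end
        )
        r.fit.to_frame(
            observed_days=result.context.post_day_index(r.series.dates[post]),
            observed=r.series.steps[post],
        ).to_csv(out / "participants" / f"{pid}_trajectory.csv", index=False)
        if r.dc is not None:
            r.dc.to_frame().to_csv(out / "participants" / f"{pid}_complexity.csv", index=False)
    if result.lag_result is not None:
        result.lag_result.to_frame().to_csv(out / "lag_scan.csv", index=False)
    with open(out / "model_report.json", "w") as fh:
        json.dump(result.model.to_dict(), fh, indent=1, default=float)
    (out / "model_report.txt").write_text(association.format_model_report(result.model) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)
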