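import numpy as np
import pytest

from stepdc import preprocess, trajectory
from stepdc.simulate import generate_toy_fixture


def process_participant(series, ctx):
    """Validity -> cap -> recode -> baseline -> growth fit -> inclusion report."""
    mask = preprocess.flag_valid_days(series)
    clean = preprocess.recode_invalid_to_missing(preprocess.cap_outliers(series), mask)
    baseline = preprocess.compute_baseline(clean, mask, ctx)
    post = (clean.dates >= ctx.lockdown_date) & (clean.dates <= ctx.observation_end)
    days = ctx.post_day_index(clean.dates[post])
    steps = clean.steps[post]
    obs = ~np.isnan(steps)
    fit = trajectory.fit_growth(days[obs], steps[obs], n_days=ctx.n_post_days)
    report = preprocess.apply_inclusion_criteria(clean, mask, fit, baseline, ctx)
    return clean, mask, baseline, fit, report


@pytest.fixture(scope="session")
def toy_cohort():
    return generate_toy_fixture()


@pytest.fixture(scope="session")
def toy_reports(toy_cohort):
    cohort, ctx = toy_cohort
    return {s.participant_id: process_participant(s, ctx)[4] for s in cohort}
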