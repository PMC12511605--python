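"""Lag scan, long-table construction, multilevel model and effect arithmetic."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from stepdc import association
from stepdc.core import ConfigurationError, InsufficientDataError
from stepdc.simulate import simulate_analysis_table


def test_lag_scan_perfect_anticorrelation_at_constructed_lag():
    rng = np.random.default_rng(0)
    dc_map, roc_map = {}, {}
    for pid in ("a", "b", "c"):
        dc = rng.uniform(0, 1, 120)
        roc = np.full(120, np.nan)
        roc[7:] = -dc[:-7]  # roc(t) = -DC(t-7) exactly
        dc_map[pid], roc_map[pid] = dc, roc
    res = association.lag_scan(dc_map, roc_map, max_lag=20)
    assert res.selected_lag == 7
    assert res.mean_correlation[6] == pytest.approx(-1.0, abs=1e-12)


def test_lag_scan_white_noise_null():
    rng = np.random.default_rng(1)
    dc_map = {f"p{i}": rng.normal(size=150) for i in range(100)}
    roc_map = {f"p{i}": rng.normal(size=150) for i in range(100)}
    res = association.lag_scan(dc_map, roc_map, max_lag=30)
    assert np.abs(res.mean_correlation).max() < 0.1


def test_lag_scan_preconditions_and_zero_variance():
    with pytest.raises(InsufficientDataError):
        association.lag_scan({"a": np.ones(50)}, {"a": np.ones(50)})
    rng = np.random.default_rng(2)
    dc_map = {"a": np.ones(100), "b": rng.normal(size=100)}
    roc_map = {"a": rng.normal(size=100), "b": -np.roll(rng.normal(size=100), 0)}
    res = association.lag_scan(dc_map, roc_map, max_lag=5)  # 'a' dropped, no crash
    assert np.isfinite(res.mean_correlation).all()


def test_build_long_table_standardization_and_alignment():
    rng = np.random.default_rng(3)
    dc_map = {f"p{i}": rng.uniform(0, 0.1, 100) for i in range(5)}
    roc_map = {f"p{i}": rng.normal(size=100) for i in range(5)}
    base = {f"p{i}": 8000 + 500 * i for i in range(5)}
    tab = association.build_long_table(dc_map, roc_map, base, lag=11)
    assert tab["ldc_z"].mean() == pytest.approx(0.0, abs=1e-9)
    assert tab["ldc_z"].std(ddof=0) == pytest.approx(1.0)
    assert np.allclose(tab["ldc_z_sq"], tab["ldc_z"] ** 2)
    assert tab["time"].min() > 0
    assert tab["time"].std(ddof=0) == pytest.approx(1.0)
    # row at day 30 with lag 11 carries DC from day 19
    row = tab[(tab.participant_id == "p0") & (tab.day == 30)]
    assert row["ldc_raw"].iloc[0] == dc_map["p0"][19]
    with pytest.raises(ConfigurationError):
        association.build_long_table(dc_map, roc_map, base, lag=0)


def test_fit_multilevel_smoke_and_shape():
    tab = simulate_analysis_table(n_participants=30, n_days=60, seed=4)
    fit = association.fit_multilevel(tab, diagonal=True)
    assert fit.n_obs == len(tab)
    assert set(fit.fixed_effects.index) == {
        "Intercept", "time", "ldc_z", "ldc_z_sq", "baseline_z"
    }
    assert (fit.fixed_effects.ci_low <= fit.fixed_effects.estimate).all()
    assert (fit.fixed_effects.estimate <= fit.fixed_effects.ci_high).all()
    assert 0.0 <= fit.icc <= 1.0
    assert fit.r2_marginal <= fit.r2_conditional
    with pytest.raises(InsufficientDataError):
        association.fit_multilevel(tab[tab.participant_id == "P0000"])


def test_estimates_invariant_to_row_and_participant_order():
    tab = simulate_analysis_table(n_participants=20, n_days=40, seed=5)
    fit1 = association.fit_multilevel(tab, diagonal=True)
    shuffled = tab.sample(frac=1.0, random_state=0).sort_values("participant_id", ascending=False, kind="stable")
    fit2 = association.fit_multilevel(shuffled, diagonal=True)
    assert np.allclose(fit1.fixed_effects.estimate, fit2.fixed_effects.estimate, atol=1e-5)


def test_compare_bic_model_selection():
    quad_wins = lin_wins = 0
    for r in range(3):
        tab = simulate_analysis_table(
            ldc_sq_effect=10.0, n_participants=50, n_days=80, seed=300 + r
        )
        b_with, b_without = association.compare_bic(tab, diagonal=True)
        quad_wins += b_with < b_without
        tab = simulate_analysis_table(
            ldc_sq_effect=0.0, re_sd=(30, 20, 10, 0.01),
            n_participants=50, n_days=80, seed=400 + r,
        )
        b_with, b_without = association.compare_bic(tab, diagonal=True)
        lin_wins += b_without <= b_with
    assert quad_wins >= 2  # majority of replicates
    assert lin_wins >= 2


@pytest.mark.parametrize(
    "b_lin, b_quad, x, expected",
    [
        (-20.42, 4.67, 1.0, -15.75),
        (-20.42, 4.67, -1.0, 25.09),
        (-24.01, 4.68, 1.0, -19.33),
        (-24.01, 4.68, -1.0, 28.69),
        (-20.42, 4.67, 0.0, 0.0),
    ],
)
def test_combined_effect_arithmetic(b_lin, b_quad, x, expected):
    assert association.combined_effect(b_lin, b_quad, x).value == pytest.approx(
        expected, abs=1e-9
    )


def test_cumulative_effect():
    eff = association.combined_effect(-20.42, 4.67, 1.0)
    assert association.cumulative_effect(28, eff) == pytest.approx(-441.0)
    eff_lo = association.combined_effect(-20.42, 4.67, -1.0)
    assert association.cumulative_effect(24, eff_lo) == pytest.approx(602.16)
    assert association.cumulative_effect(0, eff) == 0.0
    with pytest.raises(ValueError):
        association.cumulative_effect(-1, eff)


def test_moderation_analysis_recovers_attenuation():
    rng = np.random.default_rng(6)
    frames = []
    for i in range(40):
        src = "weak" if i < 20 else "ref"
        b0 = rng.normal(0, 20)
        ldc = rng.normal(0, 1, 60)
        slope = -10.0 if src == "weak" else -20.0  # halved effect in one source
        y = 50 + b0 + slope * ldc + rng.normal(0, 30, 60)
        frames.append(pd.DataFrame({
            "participant_id": f"P{i}", "time": np.arange(1, 61) / 17.0,
            "ldc_z": ldc, "ldc_z_sq": ldc ** 2, "baseline_z": rng.normal(),
            "source": src, "rate_of_change": y,
        }))
    tab = pd.concat(frames, ignore_index=True)
    fit = association.moderation_analysis(tab, "source", diagonal=True)
    # interaction term: 'weak' relative to reference level 'ref' -> positive (+10)
    est = fit.fixed_effects.loc["mod_weak_x_ldc", "estimate"]
    assert est > 0
    with pytest.raises(ConfigurationError):
        association.moderation_analysis(tab.assign(source="one"), "source")


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_fixed_effects_match_lme4(tmp_path):
    """Independent cross-check of the mixed model against lme4."""
    tab = simulate_analysis_table(n_participants=30, n_days=60, seed=8)
    fit = association.fit_multilevel(tab, reml=True, diagonal=False)
    csv = tmp_path / "tab.csv"
    tab.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
        suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
        args <- commandArgs(trailingOnly=TRUE)
        d <- read.csv(args[1])
        m <- lmer(rate_of_change ~ time + ldc_z + ldc_z_sq + baseline_z +
                  (1 + time + ldc_z + ldc_z_sq | participant_id), data=d, REML=TRUE)
        cat(toJSON(as.list(fixef(m)), digits=10, auto_unbox=TRUE))
        """
    )
    out = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    mapping = {"(Intercept)": "Intercept", "time": "time", "ldc_z": "ldc_z",
               "ldc_z_sq": "ldc_z_sq", "baseline_z": "baseline_z"}
    for r_name, name in mapping.items():
        ours = fit.fixed_effects.loc[name, "estimate"]
        assert ours == pytest.approx(ref[r_name], rel=0.05, abs=0.5), name
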