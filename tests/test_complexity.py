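"""Dynamic-complexity statistic: hand-enumerated oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepdc.complexity import (
    ScaleRange,
    distribution_parameter,
    dynamic_complexity,
    fluctuation_intensity,
    rolling_dc,
)

R10 = ScaleRange(0.0, 10.0)


# --- independent oracles: straight transcription of the definitions ---------

def naive_fluctuation(window, x_min, x_max):
    """Points of return (first point, strict extrema with plateau-end rule,
    last point); sum |diff|/intervals per monotone segment; normalise."""
    y = list(map(float, window))
    m = len(y)
    segments = []
    start, direction = 0, 0
    for i in range(1, m):
        d = y[i] - y[i - 1]
        s = (d > 0) - (d < 0)
        if s != 0 and direction != 0 and s != direction:
            segments.append((start, i - 1))
            start, direction = i - 1, s
        elif s != 0:
            direction = s
    if m - 1 > start:
        segments.append((start, m - 1))
    total = sum(abs(y[b] - y[a]) / (b - a) for a, b in segments)
    return total / ((x_max - x_min) * (m - 1))


def naive_distribution(window, x_min, x_max):
    """Exhaustive pairwise enumeration over the sorted window."""
    y = sorted(map(float, window))
    m = len(y)
    d = (x_max - x_min) / (m - 1)
    dev = ideal = 0.0
    for i in range(m - 1):
        for j in range(i + 1, m):
            ide = (j - i) * d
            dev += max(0.0, ide - (y[j] - y[i]))
            ideal += ide
    return 1.0 - dev / ideal


# --- printed toy windows -----------------------------------------------------

@pytest.mark.parametrize(
    "window, expected_f, expected_d",
    [
        ([5, 5, 5, 5], 0.0, 0.0),                       # constant: no fluctuation
        ([0, 10, 0, 10], 1.0, 0.8),                     # full-range alternation
        ([0, 0, 10, 10], 1 / 9, 0.8),                   # one monotone rise through plateaus
        ([0, 10 / 3, 20 / 3, 10], 1 / 9, 1.0),          # full-range equispaced ramp
    ],
)
def test_toy_windows_match_hand_enumeration(window, expected_f, expected_d):
    assert fluctuation_intensity(window, R10) == pytest.approx(expected_f)
    assert distribution_parameter(window, R10) == pytest.approx(expected_d)
    assert naive_fluctuation(window, 0, 10) == pytest.approx(expected_f)
    assert naive_distribution(window, 0, 10) == pytest.approx(expected_d)
    assert dynamic_complexity(window, R10) == pytest.approx(expected_f * expected_d)


def test_plateau_return_point_is_last_point_of_plateau():
    # [0,10,10,0]: segments 0->10 (2 intervals) and 10->0 (1 interval)
    assert fluctuation_intensity([0, 10, 10, 0], R10) == pytest.approx((10 / 2 + 10) / 30)


def test_range_errors_and_preconditions():
    with pytest.raises(ValueError):
        fluctuation_intensity([0, 11], R10)  # outside scale range: cap first
    with pytest.raises(ValueError):
        distribution_parameter([5.0], R10)
    with pytest.raises(ValueError):
        rolling_dc([1, 2, np.nan, 4] * 5, width=14)  # missing values: impute first
    with pytest.raises(ValueError):
        ScaleRange(5, 5)


def test_rolling_matches_naive_per_window_loop_on_random_series():
    rng = np.random.default_rng(7)
    width = 14
    rngs = ScaleRange(0.0, 40_000.0)
    for _ in range(1000):
        n = rng.integers(width, width + 12)
        series = rng.uniform(0, 40_000, n)
        out = rolling_dc(series, width=width, scale_range=rngs)
        assert np.isnan(out.dc[: width - 1]).all()
        for end in range(width - 1, n):
            w = series[end - width + 1 : end + 1]
            f = naive_fluctuation(w, 0, 40_000)
            d = naive_distribution(w, 0, 40_000)
            assert out.fluctuation[end] == pytest.approx(f, abs=1e-12)
            assert out.distribution[end] == pytest.approx(d, abs=1e-12)
            assert out.dc[end] == pytest.approx(f * d, abs=1e-12)


def test_rolling_counts_and_constant_series():
    out = rolling_dc(np.full(20, 300.0), width=14)
    defined = ~np.isnan(out.dc)
    assert defined.sum() == 7  # 20 - 14 + 1
    assert np.all(out.dc[defined] == 0.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=4, max_size=20),
    st.floats(min_value=0.1, max_value=50.0),
    st.floats(min_value=-100.0, max_value=100.0),
)
def test_affine_invariance_and_bounds(values, a, b):
    rng0 = ScaleRange(0.0, 100.0)
    rng1 = ScaleRange(b, 100.0 * a + b)
    scaled = [a * v + b for v in values]
    f0, f1 = fluctuation_intensity(values, rng0), fluctuation_intensity(scaled, rng1)
    d0, d1 = distribution_parameter(values, rng0), distribution_parameter(scaled, rng1)
    assert f1 == pytest.approx(f0, abs=1e-9)
    assert d1 == pytest.approx(d0, abs=1e-9)
    assert 0.0 <= f0 <= 1.0 + 1e-12 and 0.0 <= d0 <= 1.0 + 1e-12
    dc = dynamic_complexity(values, rng0)
    assert dc <= min(f0, d0) + 1e-12


def test_permutation_leaves_d_unchanged_but_changes_f():
    rng = np.random.default_rng(3)
    w = rng.uniform(0, 10, 14)
    perm = rng.permutation(w)
    assert distribution_parameter(perm, R10) == pytest.approx(
        distribution_parameter(w, R10)
    )
    # a sorted arrangement has strictly less fluctuation than an alternating one
    srt = np.sort(w)
    alt = np.empty_like(srt)
    alt[::2], alt[1::2] = srt[: len(srt[::2])], srt[len(srt[::2]) :][::-1]
    assert fluctuation_intensity(alt, R10) > fluctuation_intensity(srt, R10)


def test_maximisers():
    # F = 1 only under full-range alternation; D = 1 only for equispaced coverage
    alt = [0.0, 10.0] * 7
    assert fluctuation_intensity(alt, R10) == pytest.approx(1.0)
    assert fluctuation_intensity([0, 10, 0, 9], R10) < 1.0
    eq = np.linspace(0, 10, 14)
    assert distribution_parameter(eq, R10) == pytest.approx(1.0)
    assert distribution_parameter(np.sqrt(np.linspace(0, 100, 14)), R10) < 1.0
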