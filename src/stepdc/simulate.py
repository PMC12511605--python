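"""Synthetic multi-participant step-count cohorts with known ground truth.

The generator emulates the structure of multi-country wearable step data
around a lockdown-type stressor: right-skewed (log-normal) baseline daily
steps with a weekend uplift, an abrupt participant-specific drop at the
stressor date, gradual heterogeneous linear recovery, MCAR (optionally
blocked) non-wear missingness, and volatility episodes — stretches of days
with inflated noise amplitude — that raise local dynamic complexity (DC).

When ``dc_coupling`` is non-zero the recovery drift rate on day *t* is an
exact affine function of the realized local DC of the already-generated
series ``coupling_lag`` days earlier:

    rate(t) = recovery_rate_i + jitter(t) + dc_coupling * (DC(t-lag) - dc_ref) / dc_scale

so elevated-DC episodes genuinely precede slowdowns, and with zero noise the
true rate of change is perfectly (anti-)correlated with lagged DC — the
ground truth a lag scan must recover. ``dc_ref``/``dc_scale`` are fixed
standardization constants (approximate cohort mean/SD of local DC under the
default volatility regime), so ``dc_coupling`` is in steps/day per nominal
SD of DC. The rate jitter is a small AR(1) environmental wobble whose SD is
proportional to ``noise_sd``: with noisy data the recovery pace itself
varies day to day; with noise_sd = 0 the coupling is the only rate signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .complexity import ScaleRange, _dist_kernel, _fluct_kernel
from .core import STEP_CAP, ConfigurationError, StepSeries, StudyContext, cohort_to_frame

DEFAULT_LOCKDOWN = pd.Timestamp("2020-03-15")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the active adult wearable cohort the pipeline targets:
    median baseline ~10,000 steps/day, ~35% lockdown drop, ~11 steps/day
    median recovery pace, ~10% non-wear missingness.
    """

    n_participants: int = 50
    baseline_log_mean: float = float(np.log(10_000.0))
    baseline_log_sd: float = 0.30
    weekend_multiplier: float = 1.15
    lockdown_day: pd.Timestamp = DEFAULT_LOCKDOWN
    baseline_start: pd.Timestamp = pd.Timestamp("2019-10-01")
    observation_end: pd.Timestamp = pd.Timestamp("2020-09-30")
    drop_fraction_mean: float = 0.35
    drop_fraction_sd: float = 0.10
    recovery_rate_mean: float = 11.0
    recovery_rate_sd: float = 8.0
    dc_coupling: float = 0.0          # steps/day of rate per nominal SD of DC (negative = slowdown)
    coupling_lag: int = 11
    noise_sd: float = 1500.0
    burst_noise_sd: float = 4500.0    # noise amplitude inside volatility episodes
    episode_rate: float = 0.02        # per-day probability of starting an episode
    episode_length: int = 14
    rate_jitter_frac: float = 0.005   # AR(1) rate-jitter SD = frac * noise_sd
    dc_window: int = 14
    dc_ref: float = 0.01              # fixed DC standardization constants
    dc_scale: float = 0.01
    missing_rate: float = 0.10
    block_missingness: bool = False
    block_length: int = 5
    wear_minutes_model: str = "mixed"  # always_available | never | mixed
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            self.n_participants >= 1,
            0.0 <= self.drop_fraction_mean <= 1.0,
            self.drop_fraction_sd >= 0.0,
            0.0 <= self.missing_rate < 1.0,
            self.coupling_lag >= 0,
            self.noise_sd >= 0.0,
            self.burst_noise_sd >= 0.0,
            self.dc_window >= 2,
            self.dc_scale > 0.0,
            self.wear_minutes_model in ("always_available", "never", "mixed"),
        ]
        numeric = [
            self.baseline_log_mean, self.baseline_log_sd, self.weekend_multiplier,
            self.drop_fraction_mean, self.drop_fraction_sd, self.recovery_rate_mean,
            self.recovery_rate_sd, self.dc_coupling, self.noise_sd, self.burst_noise_sd,
            self.episode_rate, self.rate_jitter_frac, self.dc_ref, self.dc_scale,
            self.missing_rate,
        ]
        if not all(np.isfinite(numeric)):
            raise ConfigurationError("non-finite simulation parameter")
        if not all(checks):
            raise ConfigurationError("simulation parameter out of range")
        if self.dc_coupling != 0.0 and self.coupling_lag < 1:
            raise ConfigurationError("dc_coupling requires coupling_lag >= 1 (causal feedback)")

    @property
    def context(self) -> StudyContext:
        return StudyContext(
            lockdown_date=self.lockdown_day,
            baseline_start=self.baseline_start,
            observation_end=self.observation_end,
        )


@dataclass
class ParticipantTruth:
    participant_id: str
    baseline_level: float          # expected weekday baseline steps
    drop_fraction: float
    recovery_rate: float           # mean drift, steps/day
    rate_profile: list             # true rate of change per post-lockdown day (day 0 = NaN)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    participants: list
    time_effect: float = 0.0
    dc_linear_effect: float = 0.0
    dc_quadratic_effect: float = 0.0
    coupling_lag: int = 0

    def rate_array(self, participant_id: str) -> np.ndarray:
        for p in self.participants:
            if p.participant_id == participant_id:
                return np.asarray(p.rate_profile, dtype=float)
        raise KeyError(participant_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


def _episode_mask(rng: np.random.Generator, n: int, rate: float, length: int) -> np.ndarray:
    """High-volatility episode indicator; non-overlapping runs of `length` days."""
    mask = np.zeros(n, dtype=bool)
    t = 0
    while t < n:
        if rng.random() < rate:
            mask[t : t + length] = True
            t += length
        else:
            t += 1
    return mask


def _rate_jitter(rng: np.random.Generator, n: int, sd: float, phi: float = 0.9) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    j = np.empty(n)
    j[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, n)
    for t in range(1, n):
        j[t] = phi * j[t - 1] + eps[t]
    return j


def generate_participant(
    config: SimulationConfig, pid: str, rng: np.random.Generator, source: str, device: str,
    has_wear: bool,
) -> tuple[StepSeries, ParticipantTruth]:
    ctx = config.context
    dates = pd.date_range(ctx.baseline_start, ctx.observation_end, freq="D")
    n = len(dates)
    lock_idx = int((ctx.lockdown_date - ctx.baseline_start).days)
    n_post = n - lock_idx
    span = ScaleRange().span
    w = config.dc_window

    base = float(np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd)))
    drop = float(np.clip(rng.normal(config.drop_fraction_mean, config.drop_fraction_sd), 0.0, 1.0))
    rate0 = float(rng.normal(config.recovery_rate_mean, config.recovery_rate_sd))
    episodes = _episode_mask(rng, n, config.episode_rate, config.episode_length)
    jitter = _rate_jitter(rng, n_post, config.rate_jitter_frac * config.noise_sd)
    noise = rng.normal(0.0, 1.0, n)  # scaled per-day below
    weekend = dates.dayofweek >= 5

    steps = np.empty(n)
    dc = np.full(n, np.nan)
    rates = np.full(n_post, np.nan)
    level = 0.0
    for t in range(n):
        if t < lock_idx:
            expected = base * (config.weekend_multiplier if weekend[t] else 1.0)
        elif t == lock_idx:
            level = base * (1.0 - drop)
            expected = level
        else:
            tau = t - lock_idx
            r = rate0 + jitter[tau]
            if config.dc_coupling != 0.0:
                src = t - config.coupling_lag
                if src >= w - 1 and not np.isnan(dc[src]):
                    r += config.dc_coupling * (dc[src] - config.dc_ref) / config.dc_scale
            rates[tau] = r
            level = max(level + r, 0.0)
            expected = level
        sd = config.burst_noise_sd if episodes[t] else config.noise_sd
        steps[t] = np.rint(np.clip(expected + sd * noise[t], 0.0, STEP_CAP))
        if t >= w - 1:
            win = steps[t - w + 1 : t + 1]
            dc[t] = _fluct_kernel(win, span) * _dist_kernel(np.sort(win), span)

    wear = None
    if has_wear:
        wear = np.rint(np.clip(rng.normal(820.0, 120.0, n), 0.0, 1440.0))

    series = StepSeries(
        participant_id=pid, dates=dates, steps=steps, wear_minutes=wear,
        source=source, device=device,
    )
    if config.missing_rate > 0.0:
        series = inject_missingness(
            series, config.missing_rate, rng=rng,
            block=config.block_missingness, block_length=config.block_length,
        )
    truth = ParticipantTruth(
        participant_id=pid, baseline_level=base, drop_fraction=drop,
        recovery_rate=rate0, rate_profile=rates.tolist(),
    )
    return series, truth


def generate_cohort(config: SimulationConfig) -> tuple[list[StepSeries], GroundTruth]:
    """Generate a cohort; identical config + seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    sources = ["smart", "haie", "covicat", "open"]
    devices = ["fitbit", "fitbit", "mixed", "garmin"]
    cohort: list[StepSeries] = []
    truths: list[ParticipantTruth] = []
    for i in range(config.n_participants):
        src_i = i % len(sources)
        if config.wear_minutes_model == "always_available":
            has_wear = True
        elif config.wear_minutes_model == "never":
            has_wear = False
        else:
            has_wear = src_i in (0, 1)
        series, truth = generate_participant(
            config, f"P{i:04d}", rng, sources[src_i], devices[src_i], has_wear
        )
        cohort.append(series)
        truths.append(truth)
    gt = GroundTruth(
        participants=truths,
        time_effect=0.0,
        dc_linear_effect=config.dc_coupling,
        dc_quadratic_effect=0.0,
        coupling_lag=config.coupling_lag,
    )
    return cohort, gt


def inject_missingness(
    series: StepSeries,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    block: bool = False,
    block_length: int = 5,
) -> StepSeries:
    """Set ~`rate` of days to missing (MCAR; optional consecutive blocks)."""
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("missing rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = series.copy()
    n = len(out)
    if rate == 0.0:
        return out
    if block:
        hit = np.zeros(n, dtype=bool)
        starts = rng.random(n) < rate / block_length
        for t in np.flatnonzero(starts):
            hit[t : t + block_length] = True
    else:
        hit = rng.random(n) < rate
    out.steps = np.where(hit, np.nan, out.steps)
    return out


# ---------------------------------------------------------------------------
# deterministic toy fixture for the inclusion criteria
# ---------------------------------------------------------------------------

def _fixture_dates() -> tuple[pd.DatetimeIndex, int, StudyContext]:
    ctx = StudyContext(lockdown_date=DEFAULT_LOCKDOWN)
    dates = pd.date_range(ctx.baseline_start, ctx.observation_end, freq="D")
    return dates, int((ctx.lockdown_date - ctx.baseline_start).days), ctx


def _fixture_base(dates: pd.DatetimeIndex, lock_idx: int, post_level: float) -> np.ndarray:
    """Baseline 10,000 with a deterministic weekly wiggle; post-lockdown ramp."""
    n = len(dates)
    t = np.arange(n, dtype=float)
    wiggle = 400.0 * np.sin(2 * np.pi * t / 7.0)
    steps = np.where(
        t < lock_idx,
        10_000.0 + wiggle,
        post_level + 10.0 * (t - lock_idx) + wiggle,
    )
    return np.rint(steps)


def generate_toy_fixture() -> tuple[list[StepSeries], StudyContext]:
    """Six hand-built participants, each inclusion criterion failed by exactly one.

    - P_ok          passes all five criteria
    - P_nobaseline  only 2 valid baseline weeks (needs >= 3)
    - P_noconfine   one confinement week with just 2 valid days (needs all 4 weeks)
    - P_norecovery  weekend days removed in 11 of 24 recovery weeks (< 70% valid)
    - P_gappy       2 weekdays missing every post-lockdown week (~28% >= 20%)
    - P_noperturb   post-lockdown steps at 97% of baseline (< 10% drop)
    """
    dates, lock_idx, ctx = _fixture_dates()
    n = len(dates)
    cohort: list[StepSeries] = []

    def mk(pid: str, steps: np.ndarray) -> StepSeries:
        return StepSeries(participant_id=pid, dates=dates, steps=steps,
                          wear_minutes=None, source="toy", device="toy")

    cohort.append(mk("P_ok", _fixture_base(dates, lock_idx, 6000.0)))

    s = _fixture_base(dates, lock_idx, 6000.0)
    s[14:lock_idx] = 0.0  # invalid (< 1 step) baseline days beyond the first 2 weeks
    cohort.append(mk("P_nobaseline", s))

    s = _fixture_base(dates, lock_idx, 6000.0)
    wk2 = lock_idx + 7  # second confinement week: leave only 2 valid days
    s[wk2 + 2 : wk2 + 7] = 0.0
    cohort.append(mk("P_noconfine", s))

    s = _fixture_base(dates, lock_idx, 6000.0)
    rec_start = lock_idx + 28
    for w in range(11):  # 11 of 24 full recovery weeks lose their weekend days
        blk = rec_start + 14 * w
        if blk + 7 > n:
            break
        idx = np.arange(blk, min(blk + 7, n))
        wknd = idx[dates[idx].dayofweek >= 5]
        s[wknd] = 0.0
    cohort.append(mk("P_norecovery", s))

    s = _fixture_base(dates, lock_idx, 6000.0)
    for blk in range(lock_idx, n, 7):  # two missing weekdays per post-lockdown week
        idx = np.arange(blk, min(blk + 7, n))
        wkdy = idx[dates[idx].dayofweek < 5]
        s[wkdy[:2]] = np.nan
    cohort.append(mk("P_gappy", s))

    cohort.append(mk("P_noperturb", _fixture_base(dates, lock_idx, 9700.0)))
    return cohort, ctx


# ---------------------------------------------------------------------------
# direct simulation from the multilevel model (parameter-recovery harness)
# ---------------------------------------------------------------------------

def simulate_analysis_table(
    n_participants: int = 100,
    n_days: int = 150,
    intercept: float = 50.0,
    time_effect: float = -40.0,
    ldc_effect: float = -20.0,
    ldc_sq_effect: float = 5.0,
    baseline_effect: float = 0.0,
    re_sd: tuple = (30.0, 20.0, 10.0, 4.0),
    resid_sd: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rows drawn directly from the mixed model the association stage fits.

    Random intercept and slopes (time, ldc, ldc^2) are independent normals
    with the given SDs; ldc_z is standard normal; time is scaled (divided by
    its pooled SD) but not centered.
    """
    rng = np.random.default_rng(seed)
    t_raw = np.arange(1, n_days + 1, dtype=float)
    time = t_raw / t_raw.std()
    frames = []
    for i in range(n_participants):
        b = rng.normal(0.0, re_sd)
        ldc = rng.normal(0.0, 1.0, n_days)
        baseline_z = rng.normal()
        y = (
            intercept + b[0]
            + (time_effect + b[1]) * time
            + (ldc_effect + b[2]) * ldc
            + (ldc_sq_effect + b[3]) * ldc**2
            + baseline_effect * baseline_z
            + rng.normal(0.0, resid_sd, n_days)
        )
        frames.append(pd.DataFrame({
            "participant_id": f"P{i:04d}", "time": time, "ldc_z": ldc,
            "ldc_z_sq": ldc**2, "baseline_z": baseline_z,
            "source": "sim", "rate_of_change": y,
        }))
    return pd.concat(frames, ignore_index=True)


def write_cohort_csv(cohort: list[StepSeries], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
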