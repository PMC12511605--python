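"""Core containers and study-context configuration.

A cohort is a collection of :class:`StepSeries` — one participant's dated
daily step counts, possibly with wear-time minutes — analysed relative to a
:class:`StudyContext` that fixes the baseline window, the stressor (lockdown)
date and the end of observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STEP_CAP = 40_000
WEAR_VALID_MINUTES = 600


class ConfigurationError(ValueError):
    """A configuration value is missing, non-finite or out of range."""


class InsufficientDataError(ValueError):
    """Too few observations to carry out the requested operation."""


@dataclass(frozen=True)
class StudyContext:
    """Calendar anchors of the stressor-response study design.

    The baseline period runs from ``baseline_start`` up to (not including)
    ``lockdown_date``; the confinement period is the four weeks starting at
    the lockdown; the recovery period runs from day 28 post-lockdown through
    ``observation_end`` inclusive.
    """

    lockdown_date: pd.Timestamp
    baseline_start: pd.Timestamp = pd.Timestamp("2019-10-01")
    observation_end: pd.Timestamp = pd.Timestamp("2020-09-30")

    def __post_init__(self) -> None:
        object.__setattr__(self, "lockdown_date", pd.Timestamp(self.lockdown_date))
        object.__setattr__(self, "baseline_start", pd.Timestamp(self.baseline_start))
        object.__setattr__(self, "observation_end", pd.Timestamp(self.observation_end))
        if not self.baseline_start < self.lockdown_date < self.observation_end:
            raise ConfigurationError(
                "study dates must satisfy baseline_start < lockdown_date < observation_end"
            )

    @property
    def n_post_days(self) -> int:
        """Number of post-lockdown days, lockdown day counted as day 0."""
        return int((self.observation_end - self.lockdown_date).days) + 1

    def post_day_index(self, dates: pd.DatetimeIndex) -> np.ndarray:
        """Days since lockdown (day 0 = lockdown date) for each date."""
        return (dates - self.lockdown_date).days.to_numpy()


@dataclass
class StepSeries:
    """One participant's daily step-count series.

    ``steps`` is float-valued with NaN marking missing days; ``wear_minutes``
    is NaN where wear-time information is unavailable. Dates are a complete,
    strictly increasing daily index.
    """

    participant_id: str
    dates: pd.DatetimeIndex
    steps: np.ndarray
    wear_minutes: np.ndarray | None = None
    source: str = "synthetic"
    device: str = "synthetic"

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.steps = np.asarray(self.steps, dtype=float)
        if self.wear_minutes is not None:
            self.wear_minutes = np.asarray(self.wear_minutes, dtype=float)
            if len(self.wear_minutes) != len(self.dates):
                raise ValueError("wear_minutes length mismatch")
        if len(self.steps) != len(self.dates):
            raise ValueError("steps length mismatch")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.asi8)
            if (deltas <= 0).any():
                raise ValueError("dates must be strictly increasing")
        observed = self.steps[~np.isnan(self.steps)]
        if (observed < 0).any():
            raise ValueError("step counts must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    def copy(self) -> "StepSeries":
        return replace(
            self,
            dates=self.dates.copy(),
            steps=self.steps.copy(),
            wear_minutes=None if self.wear_minutes is None else self.wear_minutes.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: participant_id, date, steps, wear_minutes, source, device."""
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "date": self.dates.strftime("%Y-%m-%d"),
                "steps": self.steps,
                "wear_minutes": (
                    np.full(len(self), np.nan) if self.wear_minutes is None else self.wear_minutes
                ),
                "source": self.source,
                "device": self.device,
            }
        )


def cohort_to_frame(cohort: list[StepSeries]) -> pd.DataFrame:
    """Stack a cohort into one long-format table."""
    return pd.concat([s.to_frame() for s in cohort], ignore_index=True)


def cohort_from_frame(df: pd.DataFrame) -> list[StepSeries]:
    """Rebuild StepSeries objects from a long-format table.

    Expects columns participant_id, date, steps and optionally wear_minutes,
    source, device (the format written by :func:`cohort_to_frame`).
    """
    out: list[StepSeries] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("date")
        wear = None
        if "wear_minutes" in grp.columns and grp["wear_minutes"].notna().any():
            wear = grp["wear_minutes"].to_numpy(dtype=float)
        out.append(
            StepSeries(
                participant_id=str(pid),
                dates=pd.DatetimeIndex(pd.to_datetime(grp["date"])),
                steps=grp["steps"].to_numpy(dtype=float),
                wear_minutes=wear,
                source=str(grp["source"].iloc[0]) if "source" in grp.columns else "unknown",
                device=str(grp["device"].iloc[0]) if "device" in grp.columns else "unknown",
            )
        )
    return out
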