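"""Containers for fraction schedules and observed tumor-volume series.

Days are integers relative to treatment start: day 0 is the first fraction,
pretreatment scans carry negative days.  Volumes are in cc.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Schedule", "Observation", "TimeCourse"]


@dataclass(frozen=True)
class Schedule:
    """An ordered radiotherapy fraction schedule: (day, dose in Gy) pairs."""

    fractions: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.fractions]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("fraction days must be strictly increasing")
        if any(dose <= 0 for _, dose in self.fractions):
            raise ValueError("fraction doses must be positive")
        object.__setattr__(self, "fractions", tuple((int(d), float(g)) for d, g in self.fractions))

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.fractions)

    @property
    def start_day(self) -> int:
        if not self.fractions:
            raise ValueError("empty schedule has no start day")
        return self.fractions[0][0]

    @property
    def end_day(self) -> int:
        return self.fractions[-1][0]

    @property
    def total_dose(self) -> float:
        return sum(g for _, g in self.fractions)

    def __len__(self) -> int:
        return len(self.fractions)

    @classmethod
    def uniform(cls, days: list[int], dose_gy: float) -> "Schedule":
        return cls(tuple((d, dose_gy) for d in days))


@dataclass(frozen=True)
class Observation:
    """One volume sample.  Zero volume can occur in simulated (model)
    output after total kill; observed data are validated as strictly
    positive at read time."""

    day: int
    volume_cc: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.volume_cc < 0:
            raise ValueError(f"volume must be nonnegative, got {self.volume_cc} at day {self.day}")


@dataclass(frozen=True)
class TimeCourse:
    """One patient's observed (or simulated) tumor-volume series.

    Censored observations record a volume equal to the CT detection limit;
    the measurement was at or below it.
    """

    observations: tuple[Observation, ...]
    schedule: Schedule = field(default_factory=lambda: Schedule(()))
    detection_limit: float | None = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        days = [o.day for o in obs]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("observation days must be nondecreasing")
        for o in obs:
            if o.censored:
                if self.detection_limit is None:
                    raise ValueError("censored observation requires a detection limit")
                if abs(o.volume_cc - self.detection_limit) > 1e-12:
                    raise ValueError(
                        "censored observations must carry volume equal to the detection limit"
                    )
        object.__setattr__(self, "observations", obs)

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(o.day for o in self.observations)

    @property
    def volumes(self) -> tuple[float, ...]:
        return tuple(o.volume_cc for o in self.observations)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def pretreatment_available(self) -> bool:
        """True when at least one scan precedes the first fraction (day 0)."""
        return any(o.day < 0 for o in self.observations)
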