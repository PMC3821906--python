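"""Synthetic treatment schedules and noisy tumor-volume time courses.

Emulates the data structure the fitting pipeline assumes: exponential
pretreatment growth, a fraction calendar (weekday 1.8-2.5 Gy fractions over
6-10 weeks for group L, five 10 Gy fractions inside two weeks for group S),
daily pre-fraction CT volumes plus a planning scan and follow-ups,
multiplicative lognormal measurement noise in the 5-10% range, and a CT
detection limit below which measurements are censored to the limit.

The generator is deterministic given the scenario seed and returns the
noiseless ground truth alongside the noisy series, so parameter-recovery
and coverage studies can compare fits against the generating model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fixtures import best_fits, effect_from_fit, growth_from_fit
from .kinetics import GrowthParams, simulate
from .timecourse import Observation, Schedule, TimeCourse
from .treatment import EffectModel

__all__ = ["ScenarioSpec", "make_schedule", "generate_timecourse", "archetype_suite"]

#: Hypofractionated courses finish in under 14 days by definition.
MAX_S_COURSE_DAYS = 13

#: Default multiplicative noise CV: middle of the observed 5-10% range.
DEFAULT_NOISE_CV = 0.07

#: Default CT detection limit in cc (configurable; small lesions only).
DEFAULT_DETECTION_LIMIT = 0.1


def _spread(n: int, candidates: list[int]) -> list[int]:
    """Pick n days from candidates, evenly spread, keeping first and last."""
    if n > len(candidates):
        raise ValueError(f"cannot place {n} fractions on {len(candidates)} available days")
    if n == 1:
        return [candidates[0]]
    idx = np.round(np.linspace(0, len(candidates) - 1, n)).astype(int)
    days = [candidates[i] for i in sorted(set(int(i) for i in idx))]
    if len(days) != n:
        raise ValueError(f"cannot place {n} strictly increasing fractions in the given span")
    return days


def make_schedule(
    group: str,
    total_days: int,
    segments: tuple[tuple[int, float], ...] | None = None,
) -> Schedule:
    """Build a fraction calendar spanning ``total_days`` calendar days.

    Group L: fractions on weekdays (treatment starts on a Monday, day 0),
    defaulting to 30 x 2.5 Gy; when the span exceeds the fraction count the
    course is stretched by evenly spaced treatment breaks.  Group S: five
    10 Gy fractions with 1-3 day gaps, completed in under 14 days.
    ``segments`` overrides the dose structure, e.g. ((20, 2.5), (15, 2.0)).
    """
    if group == "S":
        if total_days > MAX_S_COURSE_DAYS:
            raise ValueError(
                f"group S courses complete in under 14 days, got {total_days}"
            )
        segments = segments or ((5, 10.0),)
        candidates = list(range(total_days))
    elif group == "L":
        segments = segments or ((30, 2.5),)
        candidates = [d for d in range(total_days) if d % 7 < 5]
    else:
        raise ValueError(f"unknown treatment group {group!r}")
    n = sum(int(k) for k, _ in segments)
    days = _spread(n, candidates)
    doses: list[float] = []
    for k, dose in segments:
        doses.extend([dose] * int(k))
    return Schedule(tuple(zip(days, doses)))


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated patient: kinetics, treatment model, and sampling plan."""

    group: str
    growth: GrowthParams
    effect: EffectModel
    V0: float
    schedule: Schedule
    planning_scan_day: int = -14
    followup_days: tuple[int, ...] = ()
    noise_cv: float = DEFAULT_NOISE_CV
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    seed: int = 0
    name: str = ""
    intended_type: str | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be nonnegative, got {self.noise_cv}")
        if self.V0 <= self.detection_limit:
            raise ValueError("V0 must exceed the detection limit")
        if self.planning_scan_day > 0:
            raise ValueError("planning scan precedes treatment start (day <= 0)")

    @property
    def sample_days(self) -> tuple[int, ...]:
        days = {self.planning_scan_day}
        days.update(self.schedule.days)
        days.update(self.followup_days)
        return tuple(sorted(days))


def generate_timecourse(spec: ScenarioSpec) -> tuple[TimeCourse, TimeCourse]:
    """Simulate a scenario and return (noisy series, noiseless ground truth).

    Volumes are sampled pre-fraction on every treatment day, at the planning
    scan, and at follow-ups; each is multiplied by a median-one lognormal
    factor whose coefficient of variation is ``noise_cv`` (so on the log
    scale errors are Gaussian, matching the likelihood the fits assume).
    Noisy values at or below the detection limit are recorded at the limit
    with the censored flag set.
    """
    days = spec.sample_days
    t_span = (min(days[0], 0), max(days[-1], spec.schedule.end_day if len(spec.schedule) else 0))
    truth = simulate(
        spec.growth, spec.effect, spec.schedule, spec.V0, t_span, days, patient_id=spec.name
    )
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    obs = []
    for o in truth.observations:
        v = o.volume_cc * math.exp(sigma * rng.standard_normal()) if sigma > 0 else o.volume_cc
        if v <= spec.detection_limit:
            obs.append(Observation(day=o.day, volume_cc=spec.detection_limit, censored=True))
        else:
            obs.append(Observation(day=o.day, volume_cc=v))
    noisy = TimeCourse(
        observations=tuple(obs),
        schedule=spec.schedule,
        detection_limit=spec.detection_limit,
        patient_id=spec.name,
    )
    return noisy, truth


def archetype_suite(seed: int = 0, noise_cv: float = DEFAULT_NOISE_CV) -> list[ScenarioSpec]:
    """The standard regression battery: one scenario per response type per
    group where it occurs (A, B, C in group L; A-D in group S).

    Each scenario is parameterized from a representative best-fit patient of
    the reference cohort, with that patient's course calendar, a planning
    scan two weeks before treatment, and follow-ups one and two months
    after the last fraction.
    """
    # (name, patient row id, intended type, course days, resistance variant)
    picks = [
        ("L-A", "L5", "A"),
        ("L-B", "L3", "B"),
        ("L-C", "L2", "C"),
        ("S-A", "S1", "A"),
        ("S-B", "S2", "B"),
        ("S-C", "S5", "C"),
        ("S-D", "S3", "D"),
    ]
    rows = {r["patient"]: r for r in best_fits()}
    from .fixtures import COHORT_COURSES

    courses = {r["patient"]: r for r in COHORT_COURSES}
    out = []
    for i, (name, pid, rtype) in enumerate(picks):
        row = rows[pid]
        course = courses[pid]
        sched = make_schedule(row["group"], course["days_to_finish"], segments=course["segments"])
        last = sched.end_day
        # short courses add an early post-treatment diagnostic scan: with
        # only five treatment-day CTs the richer models would otherwise
        # have as many free parameters as observations
        followups = (last + 14, last + 30, last + 60) if row["group"] == "S" else (last + 30, last + 60)
        out.append(
            ScenarioSpec(
                group=row["group"],
                growth=growth_from_fit(row),
                effect=effect_from_fit(row),
                V0=row["v0"],
                schedule=sched,
                planning_scan_day=-14,
                followup_days=followups,
                noise_cv=noise_cv,
                seed=(seed * 1009 + i) % 2**31,
                name=name,
                intended_type=rtype,
            )
        )
    return out
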