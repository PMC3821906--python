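"""Shared fixtures: small deterministic scenarios and fast fit configs."""
from __future__ import annotations

import pytest

from rtkinetics.fitting import FitConfig
from rtkinetics.kinetics import GrowthParams
from rtkinetics.synthetic import ScenarioSpec, make_schedule
from rtkinetics.treatment import EffectModel


@pytest.fixture
def fast_cfg() -> FitConfig:
    """Fit config sized for unit tests (few starts, fixed seed)."""
    return FitConfig(multistart=3, seed=0)


def minimal_scenario(
    seed: int = 1,
    noise_cv: float = 0.0,
    K: float = 15.0,
    D: float = 0.5,
    Td: float = 200.0,
    V0: float = 8.5,
    group: str = "L",
    course_days: int = 42,
) -> ScenarioSpec:
    """A conventional-fractionation patient under the minimal model.

    The detection limit sits far below the trajectory so no observation is
    censored (recovery oracles need unbiased data).
    """
    sched = make_schedule(group, course_days)
    return ScenarioSpec(
        group=group,
        growth=GrowthParams.single_population(Td),
        effect=EffectModel(tag="M", K=K, D=D),
        V0=V0,
        schedule=sched,
        planning_scan_day=-14,
        followup_days=(sched.end_day + 14, sched.end_day + 30),
        noise_cv=noise_cv,
        detection_limit=1e-4,
        seed=seed,
    )


def short_course_scenario(
    seed: int = 1,
    noise_cv: float = 0.05,
    K: float = 15.0,
    D: float = 0.5,
    Td: float = 200.0,
    V0: float = 8.5,
) -> ScenarioSpec:
    """A hypofractionated patient (5 x 10 Gy in 9 days) under the minimal
    model, with follow-ups out to two months."""
    sched = make_schedule("S", 9)
    return ScenarioSpec(
        group="S",
        growth=GrowthParams.single_population(Td),
        effect=EffectModel(tag="M", K=K, D=D),
        V0=V0,
        schedule=sched,
        planning_scan_day=-14,
        followup_days=(14, 21, 30, 45, 60),
        noise_cv=noise_cv,
        detection_limit=1e-4,
        seed=seed,
    )
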