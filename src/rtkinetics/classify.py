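"""Response typing of fitted patients on a 2x2 kill/dying-rate grid.

Kill per fraction (K of the minimal family or Kp of the standard family) is
"high" at or above a group-specific threshold — 5% under conventional
fractionation (group L), 35% under hypofractionation (group S) — and the
dying process is "fast" when D >= 0.5/day.  Types: A = high/slow,
B = high/fast, C = low/slow (or dying rate not detectable), D = low/fast.
C and D are the poor responders.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

__all__ = ["KILL_THRESHOLD", "FAST_DYING_THRESHOLD", "ResponseType", "classify", "classify_cohort"]

#: Per-fraction kill percentage at or above which the kill is "high".
KILL_THRESHOLD = {"L": 5.0, "S": 35.0}

#: Dying rate at or above which the dying process is "fast".
FAST_DYING_THRESHOLD = 0.5

_LABEL = {("high", "slow"): "A", ("high", "fast"): "B", ("low", "slow"): "C", ("low", "fast"): "D"}


@dataclass(frozen=True)
class ResponseType:
    label: str
    kill_class: str  # "high" | "low"
    dying_class: str  # "fast" | "slow" (slow includes "not detectable")


def classify(group: str, kill: float, D: float | None) -> ResponseType:
    """Type a fitted response from its kill percentage and dying rate.

    ``kill`` is K or Kp (the rule treats them interchangeably) in percent;
    ``D`` may be ``None`` when the dying rate was not detectable, which
    routes to the slow branch.  Threshold comparisons are inclusive.
    """
    if group not in KILL_THRESHOLD:
        raise ValueError(f"unknown treatment group {group!r}; expected 'L' or 'S'")
    if not 0 <= kill <= 100:
        raise ValueError(f"kill must be a percentage in [0, 100], got {kill}")
    if D is not None and not 0 < D <= 1:
        raise ValueError(f"dying rate must be in (0, 1] or None, got {D}")
    kill_class = "high" if kill >= KILL_THRESHOLD[group] else "low"
    dying_class = "fast" if D is not None and D >= FAST_DYING_THRESHOLD else "slow"
    return ResponseType(label=_LABEL[(kill_class, dying_class)], kill_class=kill_class, dying_class=dying_class)


def classify_cohort(items: Iterable[tuple[str, float, float | None]]) -> dict[str, Counter]:
    """Count response types per group.

    ``items`` yields (group, kill percent, dying rate or None) per patient,
    one best-fit model each.  Returns {"L": Counter, "S": Counter} with
    counts over labels A-D (zero-filled).
    """
    counts = {g: Counter({lab: 0 for lab in "ABCD"}) for g in KILL_THRESHOLD}
    for group, kill, D in items:
        counts[group][classify(group, kill, D).label] += 1
    return counts
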