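"""Linear-quadratic fractionation bookkeeping: BED and EQD2.

For a course of segments (n fractions of d Gy each) and an alpha/beta ratio
(Gy), the biologically effective dose is BED = sum n·d·(1 + d/ab) and the
equivalent dose in 2 Gy fractions is EQD2 = sum n·d·(d + ab)/(2 + ab), so
EQD2 = BED/(1 + 2/ab) identically.
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FractionationCourse", "bed", "eqd2"]


@dataclass(frozen=True)
class FractionationCourse:
    """A fractionation course: ((n, dose_gy), ...) segments and alpha/beta."""

    segments: tuple[tuple[int, float], ...]
    alpha_beta: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha/beta must be positive, got {self.alpha_beta}")
        segs = []
        for n, d in self.segments:
            if int(n) != n or n < 1:
                raise ValueError(f"fraction count must be a positive integer, got {n}")
            if d <= 0:
                raise ValueError(f"dose per fraction must be positive, got {d}")
            segs.append((int(n), float(d)))
        object.__setattr__(self, "segments", tuple(segs))

    @property
    def total_dose(self) -> float:
        return sum(n * d for n, d in self.segments)


def bed(course: FractionationCourse) -> float:
    """Biologically effective dose (Gy) of the course."""
    ab = course.alpha_beta
    return sum(n * d * (1.0 + d / ab) for n, d in course.segments)


def eqd2(course: FractionationCourse) -> float:
    """Equivalent total dose (Gy) if delivered in 2 Gy fractions."""
    ab = course.alpha_beta
    return sum(n * d * (d + ab) / (2.0 + ab) for n, d in course.segments)
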