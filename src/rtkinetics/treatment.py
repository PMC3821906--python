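"""Radiotherapy-efficacy models applied at fraction times.

Four families, in increasing complexity:

* ``M`` (minimal): a fraction kills ``K`` percent of all live sensitive
  cells, with no distinction between cycling and quiescent cells.
* ``St`` (standard): separate per-fraction kill of cycling (``Kp``) and
  quiescent (``Kq``) cells.
* recruitment (``MRec``/``StRec``): during a window after treatment start
  the quiescent re-entry rate is replaced by an elevated ``gamma_rec``
  (> 0.01/day), modelling accelerated repopulation of the cycling pool.
* resistance (``MResInit``/``StResInit``: a fraction ``Rini`` of cells is
  radioresistant from the outset; ``MResInd``/``StResInd``: a fraction
  ``Rind`` of surviving sensitive cells becomes resistant at each
  fraction).  Resistant cells grow like sensitive ones but are never
  killed.

Killed cells move to the first dying stage and leave the tumor only after
traversing the three-stage dying pipeline at rate ``D`` per day.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .kinetics import GAMMA_PRETREATMENT_MAX, GrowthParams, PopulationState

__all__ = ["EffectModel", "apply_fraction", "effective_gamma", "model_parameter_count", "MODEL_TAGS"]

MODEL_TAGS = ("M", "St", "MRec", "StRec", "MResInit", "MResInd", "StResInit", "StResInd")


@dataclass(frozen=True)
class EffectModel:
    """A tagged treatment-efficacy variant with its parameters.

    Kill parameters ``K``/``Kp``/``Kq`` are percentages per fraction; ``D``
    is the daily dying-stage advance rate; ``gamma_rec`` (with
    ``rec_window``, days relative to treatment start, end ``None`` = open)
    configures recruitment; ``Rini``/``Rind`` configure resistance.  Fields
    not enabled by the tag are ignored and must stay at their defaults.
    """

    tag: str
    K: float = 0.0
    Kp: float = 0.0
    Kq: float = 0.0
    D: float = 1.0
    gamma_rec: float | None = None
    rec_window: tuple[int, int | None] | None = None
    Rini: float = 0.0
    Rind: float = 0.0

    def __post_init__(self) -> None:
        if self.tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.tag!r}; expected one of {MODEL_TAGS}")
        for name in ("K", "Kp", "Kq"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
        if not 0 < self.D <= 1:
            raise ValueError(f"dying rate D must be in (0, 1], got {self.D}")
        if self.has_recruitment:
            if self.gamma_rec is None or self.rec_window is None:
                raise ValueError(f"{self.tag} requires gamma_rec and rec_window")
            if self.gamma_rec <= GAMMA_PRETREATMENT_MAX:
                raise ValueError(
                    f"gamma_rec must exceed the pretreatment maximum {GAMMA_PRETREATMENT_MAX}"
                )
        if not 0 <= self.Rini < 1:
            raise ValueError(f"Rini must be in [0, 1), got {self.Rini}")
        if not 0 <= self.Rind < 1:
            raise ValueError(f"Rind must be in [0, 1), got {self.Rind}")
        if self.Rini > 0 and not self.tag.endswith("ResInit"):
            raise ValueError(f"Rini set but tag {self.tag} has no initial resistance")
        if self.Rind > 0 and not self.tag.endswith("ResInd"):
            raise ValueError(f"Rind set but tag {self.tag} has no induced resistance")

    # -- tag structure -------------------------------------------------
    @property
    def family(self) -> str:
        """"M" or "St": whether kill distinguishes cycling from quiescent."""
        return "St" if self.tag.startswith("St") else "M"

    @property
    def has_recruitment(self) -> bool:
        return self.tag.endswith("Rec")

    @property
    def has_resistance(self) -> bool:
        return "Res" in self.tag

    @property
    def kill_fractions(self) -> tuple[float, float]:
        """(cycling, quiescent) kill fractions in [0, 1] for one fraction."""
        if self.family == "M":
            return self.K / 100.0, self.K / 100.0
        return self.Kp / 100.0, self.Kq / 100.0

    # -- behaviour -----------------------------------------------------
    def apply(self, s: PopulationState) -> PopulationState:
        return apply_fraction(s, self)

    def gamma_at(self, t: float, g: GrowthParams) -> float:
        return effective_gamma(self, g, t)


def apply_fraction(s: PopulationState, e: EffectModel) -> PopulationState:
    """Instantaneous effect of one radiation fraction.

    Sensitive cycling/quiescent cells are reduced by their kill fractions
    and the killed cells enter dying stage I.  Under induced resistance a
    fraction ``Rind`` of the *surviving* sensitive cells transfers to the
    resistant compartments.  Resistant and already-dying cells are never
    reduced by a fraction.
    """
    kp, kq = e.kill_fractions
    killed = kp * s.Np + kq * s.Nq
    surv_p = (1.0 - kp) * s.Np
    surv_q = (1.0 - kq) * s.Nq
    rind = e.Rind if e.tag.endswith("ResInd") else 0.0
    return replace(
        s,
        Np=surv_p * (1.0 - rind),
        Nq=surv_q * (1.0 - rind),
        Nrp=s.Nrp + surv_p * rind,
        Nrq=s.Nrq + surv_q * rind,
        Nd1=s.Nd1 + killed,
    )


def effective_gamma(e: EffectModel, g: GrowthParams, t: float) -> float:
    """Quiescent re-entry rate in force on day ``t`` after treatment start.

    Returns ``gamma_rec`` inside the recruitment window of a Rec-family
    model, the pretreatment ``gamma`` otherwise.
    """
    if not e.has_recruitment:
        return g.gamma
    if e.rec_window is None:
        raise ValueError("recruitment model without a configured window")
    start, end = e.rec_window
    if t >= start and (end is None or t <= end):
        return e.gamma_rec
    return g.gamma


def model_parameter_count(
    e: EffectModel,
    pretreatment_data: bool = True,
    gamma_free: bool = False,
) -> int:
    """Number of free parameters for a fit of this model configuration.

    Counts V0 and the kill/dying parameters always; Td only when a
    pretreatment scan allows estimating it; GF and Tpot for the St family;
    gamma only when explicitly freed (it is fixed, normally at 0, by
    default); plus one for gamma_rec or Rini/Rind where enabled.  The noise
    scale sigma is profiled out and never counted.
    """
    n = 1  # V0
    if pretreatment_data:
        n += 1  # Td
    if e.family == "St":
        n += 2  # GF, Tpot (or Tc)
    if gamma_free:
        n += 1
    n += 1 if e.family == "M" else 2  # K | Kp, Kq
    n += 1  # D
    if e.has_recruitment:
        n += 1
    if e.has_resistance:
        n += 1
    return n
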