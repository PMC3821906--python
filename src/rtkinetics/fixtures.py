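"""Reference cohort: published course descriptors and best-fit parameters.

Seventeen NSCLC patients imaged daily during radiotherapy: group L received
conventional fractionation (1.8-2.5 Gy weekday fractions over 43-70 days),
group S a hypofractionated course (5 x 10 Gy completed in under 14 days).
``COHORT_COURSES`` holds the treatment-course descriptors; ``COHORT_FITS``
the per-patient best-fit kinetic parameters (with alternates where two
models were statistically indistinguishable).  These values anchor the
synthetic-data archetypes and the regression tests.

Units: volumes cc, times days, kill parameters percent per fraction, rates
per day.  ``Rind`` is stored as a fraction (the published percentages / 100).
``None`` marks values not estimable from the data ("ND") or not applicable
to the model family.  Recruitment windows are (start, end) days after
treatment start, ``None`` end = until last observation.
"""
from __future__ import annotations

from .kinetics import GrowthParams
from .timecourse import Schedule
from .treatment import EffectModel

__all__ = [
    "COHORT_COURSES",
    "COHORT_FITS",
    "best_fits",
    "response_items",
    "growth_from_fit",
    "effect_from_fit",
]

# patient, group, segments ((n fractions, Gy), ...), printed BED10 (Gy),
# calendar days from first to last fraction inclusive
COHORT_COURSES: tuple[dict, ...] = (
    {"patient": "L1", "group": "L", "segments": ((30, 2.5),), "bed10": 93.8, "days_to_finish": 46},
    {"patient": "L2", "group": "L", "segments": ((30, 2.5),), "bed10": 93.8, "days_to_finish": 43},
    {"patient": "L3", "group": "L", "segments": ((30, 2.5),), "bed10": 93.8, "days_to_finish": 44},
    {"patient": "L4", "group": "L", "segments": ((20, 2.5), (15, 2.0)), "bed10": 98.5, "days_to_finish": 70},
    {"patient": "L5", "group": "L", "segments": ((37, 1.8),), "bed10": 78.6, "days_to_finish": 55},
    {"patient": "S1", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 12},
    {"patient": "S2", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 9},
    {"patient": "S3", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 9},
    {"patient": "S4", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 11},
    {"patient": "S5", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 12},
    {"patient": "S6", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 12},
    {"patient": "S7", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 12},
    {"patient": "S8", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 9},
    {"patient": "S10", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 9},
    {"patient": "S11", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 11},
    {"patient": "S12", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 9},
    {"patient": "S13", "group": "S", "segments": ((5, 10.0),), "bed10": 100.0, "days_to_finish": 9},
)


def _fit(patient, group, v0, model, best, rtype, Td=None, GF=None, Tpot=None,
         gamma=None, gamma_rec=None, rec_window=None, K=None, Kp=None, Kq=None,
         D=None, Rini=None, Rind=None, delta_pct=None):
    return dict(
        patient=patient, group=group, v0=v0, model=model, best=best,
        response_type=rtype, Td=Td, GF=GF, Tpot=Tpot, gamma=gamma,
        gamma_rec=gamma_rec, rec_window=rec_window, K=K, Kp=Kp, Kq=Kq, D=D,
        Rini=Rini, Rind=Rind, delta_pct=delta_pct,
    )


# The M-family resistance rows carry both resistance variants (the data did
# not distinguish them): Rini for the initial, Rind for the induced model.
COHORT_FITS: tuple[dict, ...] = (
    _fit("L1", "L", 8.5, "MRes", True, "B", Td=200, Tpot=5.6, K=15, D=0.5,
         Rini=0.20, Rind=0.034, delta_pct=8.0),
    _fit("L1", "L", 8.5, "StRec", False, "B", Td=200, GF=0.15, Tpot=13.9,
         gamma=0.01, gamma_rec=0.10, rec_window=(21, None), Kp=29, Kq=1,
         D=0.56, delta_pct=7.0),
    _fit("L2", "L", 13.2, "M", True, "C", Td=100, Tpot=9.3, K=1.8, D=0.2,
         delta_pct=3.5),
    _fit("L3", "L", 4.6, "StRec", True, "B", Td=400, GF=0.05, Tpot=27.8,
         gamma=0.0, gamma_rec=0.37, rec_window=(1, 13), Kp=49, Kq=1, D=0.6,
         delta_pct=10.2),
    _fit("L4", "L", 161.1, "MRes", True, "A", Td=1000, Tpot=5.5, K=10, D=0.3,
         Rini=0.31, Rind=0.032, delta_pct=4.0),
    _fit("L5", "L", 1.8, "MRes", True, "A", Td=150, Tpot=5.6, K=16, D=0.35,
         Rini=0.36, Rind=0.062, delta_pct=5.1),
    _fit("L5", "L", 1.8, "StRec", False, "A", Td=150, GF=0.25, Tpot=5.6,
         gamma=0.0, gamma_rec=0.02, rec_window=(14, None), Kp=7, Kq=1, D=0.36,
         delta_pct=5.4),
    _fit("S1", "S", 3.2, "St", True, "A", Td=25, GF=0.06, Tpot=22.8, gamma=0.0,
         Kp=90, Kq=5, D=0.2, delta_pct=8.4),
    _fit("S2", "S", 12.1, "StRec", True, "B", Td=25, GF=0.10, Tpot=14.3,
         gamma=0.0, gamma_rec=0.26, rec_window=(1, 3), Kp=90, Kq=1, D=1.0,
         delta_pct=6.8),
    _fit("S3", "S", 2.0, "M", True, "D", Td=250, Tpot=5.6, K=8, D=0.999,
         delta_pct=6.6),
    _fit("S4", "S", 2.0, "M", True, "C", Td=None, K=25, D=None, delta_pct=4.0),
    _fit("S5", "S", 23.5, "M", True, "C", Td=150, Tpot=8.4, K=9, D=0.2,
         delta_pct=3.7),
    _fit("S5", "S", 23.5, "St", False, "C", Td=150, Tpot=8.4, Kp=90, Kq=2,
         D=0.2, delta_pct=5.1),
    _fit("S6", "S", 8.1, "M", True, "D", Td=45, Tpot=5.6, K=13, D=1.0,
         delta_pct=6.6),
    _fit("S7", "S", 4.7, "St", True, "A", Td=30, GF=0.06, Tpot=23.6, gamma=0.0,
         Kp=99, Kq=23, D=0.2, delta_pct=9.2),
    _fit("S8", "S", 1.2, "StRec", True, "B", Td=1000, GF=0.05, Tpot=27.7,
         gamma=0.0, gamma_rec=0.48, rec_window=(1, 3), Kp=65, Kq=1, D=0.9,
         delta_pct=7.2),
    _fit("S10", "S", 3.2, "St", True, "A", Td=15, Tpot=9.7, gamma=0.01, Kp=99,
         Kq=23, D=0.2, delta_pct=13.1),
    _fit("S11", "S", 1.7, "M", True, "D", Td=15, Tpot=5.8, K=22, D=0.99,
         delta_pct=23.9),
    _fit("S12", "S", 0.7, "StRec", True, "B", Td=75, GF=0.05, Tpot=28.0,
         gamma=0.0, gamma_rec=0.74, rec_window=(1, 3), Kp=76, Kq=0.01, D=0.75,
         delta_pct=7.2),
    _fit("S13", "S", 4.1, "St", True, "A", Td=1000, Tpot=5.5, Kp=90, Kq=53,
         D=0.2, delta_pct=14.6),
)


def best_fits() -> tuple[dict, ...]:
    """The best-fit row per patient (the first-listed where alternates exist)."""
    return tuple(r for r in COHORT_FITS if r["best"])


def response_items() -> list[tuple[str, float, float | None]]:
    """(group, kill percent, dying rate) per patient for cohort typing."""
    out = []
    for r in best_fits():
        kill = r["K"] if r["K"] is not None else r["Kp"]
        out.append((r["group"], kill, r["D"]))
    return out


def growth_from_fit(row: dict) -> GrowthParams:
    """Growth parameters implied by a fit row.

    M-family rows determine only Td (kill is uniform, so the cycling/
    quiescent split does not affect the volume trajectory) and map to a
    single-population kernel; St-family rows need Td, GF, Tpot.
    """
    if row["Td"] is None:
        raise ValueError(f"patient {row['patient']}: doubling time not estimable")
    if row["model"].startswith("St"):
        if row["GF"] is None or row["Tpot"] is None:
            raise ValueError(f"patient {row['patient']}: GF/Tpot not available")
        return GrowthParams.from_tpot(row["Td"], row["GF"], row["Tpot"], gamma=row["gamma"] or 0.0)
    return GrowthParams.single_population(row["Td"])


def effect_from_fit(row: dict, resistance: str = "initial") -> EffectModel:
    """Treatment-efficacy model from a fit row.

    ``resistance`` selects which of the two indistinguishable resistance
    variants ("initial" or "induced") to instantiate for Res rows.
    """
    tag = row["model"]
    kw: dict = {"D": row["D"] if row["D"] is not None else 1.0}
    if tag.startswith("St"):
        kw.update(Kp=row["Kp"], Kq=row["Kq"])
    else:
        kw.update(K=row["K"])
    if tag.endswith("Rec"):
        kw.update(gamma_rec=row["gamma_rec"], rec_window=row["rec_window"])
    if tag.endswith("Res"):
        if resistance == "initial":
            tag = tag + "Init"
            kw.update(Rini=row["Rini"])
        else:
            tag = tag + "Ind"
            kw.update(Rind=row["Rind"])
    return EffectModel(tag=tag, **kw)


def course_schedule(patient: str) -> Schedule:
    """Calendar schedule for a cohort patient, reconstructed from the course
    descriptor (weekday pattern for group L, spaced large fractions for S)."""
    from .synthetic import make_schedule  # local import to avoid a cycle

    row = next(r for r in COHORT_COURSES if r["patient"] == patient)
    return make_schedule(row["group"], row["days_to_finish"], segments=row["segments"])
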