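"""Delimited-text input/output for time courses, schedules and fit reports.

Time-course files are CSV with columns ``patient_id, day, volume_cc,
censored``; schedule files have ``patient_id, day, dose_gy`` (the
patient_id column may be omitted in single-patient files).  Days are
integers relative to treatment start (day 0 = first fraction, pretreatment
negative).
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .timecourse import Observation, Schedule, TimeCourse

__all__ = ["read_timecourse", "read_cohort", "read_schedules", "write_timecourse",
           "write_schedule", "report_frame", "write_report"]

log = logging.getLogger("rtkinetics")

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def _parse_censored(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in ("nan", "none"):
        return False
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}: unparseable censored flag {value!r}")


def read_schedules(path) -> dict[str, Schedule]:
    """Read a fraction-schedule CSV, keyed by patient (or '' if unkeyed)."""
    df = pd.read_csv(path)
    required = {"day", "dose_gy"}
    if not required.issubset(df.columns):
        raise ValueError(f"schedule file {path} must have columns {sorted(required)}")
    if "patient_id" not in df.columns:
        df["patient_id"] = ""
    out = {}
    for pid, sub in df.groupby("patient_id", sort=False):
        sub = sub.sort_values("day")
        out[str(pid)] = Schedule(tuple(zip(sub["day"].astype(int), sub["dose_gy"].astype(float))))
    return out


def read_cohort(path, schedule_path=None, detection_limit: float | None = None) -> dict[str, TimeCourse]:
    """Read a (possibly multi-patient) time-course CSV.

    Censored rows whose volume differs from the detection limit are reset
    to the limit with a warning (the conservative convention the fits use).
    When no detection limit is supplied, the smallest censored volume in
    each series is taken as that series' limit.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "day", "volume_cc", "censored"}
    if not required.issubset(df.columns):
        raise ValueError(f"time-course file {path} must have columns {sorted(required)}")
    schedules = read_schedules(schedule_path) if schedule_path else {}
    out: dict[str, TimeCourse] = {}
    for pid, sub in df.groupby("patient_id", sort=False):
        pid = str(pid)
        sub = sub.reset_index(drop=True)
        obs = []
        for i, row in sub.iterrows():
            day = row["day"]
            if float(day) != int(day):
                raise ValueError(f"patient {pid} row {i}: day {day} is not an integer")
            vol = float(row["volume_cc"])
            if not vol > 0:
                raise ValueError(f"patient {pid} row {i}: nonpositive volume {vol}")
            obs.append((int(day), vol, _parse_censored(row["censored"], i)))
        days = [d for d, _, _ in obs]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError(f"patient {pid}: observation days are not sorted")
        limit = detection_limit
        if limit is None and any(c for _, _, c in obs):
            limit = min(v for _, v, c in obs if c)
        fixed_obs = []
        for day, vol, cens in obs:
            if cens and abs(vol - limit) > 1e-12:
                log.warning(
                    "patient %s day %d: censored volume %.4g reset to detection limit %.4g",
                    pid, day, vol, limit,
                )
                vol = limit
            fixed_obs.append(Observation(day=day, volume_cc=vol, censored=cens))
        sched = schedules.get(pid, schedules.get("", Schedule(())))
        out[pid] = TimeCourse(
            observations=tuple(fixed_obs), schedule=sched,
            detection_limit=limit, patient_id=pid,
        )
    return out


def read_timecourse(path, schedule_path=None, detection_limit: float | None = None) -> TimeCourse:
    """Read a single-patient time-course CSV (error if several patients)."""
    cohort = read_cohort(path, schedule_path, detection_limit)
    if len(cohort) != 1:
        raise ValueError(f"{path} holds {len(cohort)} patients; expected exactly one")
    return next(iter(cohort.values()))


def write_timecourse(tc: TimeCourse, path) -> None:
    pd.DataFrame(
        {
            "patient_id": tc.patient_id,
            "day": [o.day for o in tc.observations],
            "volume_cc": [o.volume_cc for o in tc.observations],
            "censored": [o.censored for o in tc.observations],
        }
    ).to_csv(path, index=False)


def write_schedule(sched: Schedule, path, patient_id: str = "") -> None:
    pd.DataFrame(
        {
            "patient_id": patient_id,
            "day": [d for d, _ in sched.fractions],
            "dose_gy": [g for _, g in sched.fractions],
        }
    ).to_csv(path, index=False)


_REPORT_PARAMS = ("V0", "Td", "GF", "Tpot", "gamma", "gamma_rec",
                  "K", "Kp", "Kq", "D", "Rini", "Rind")


def report_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble the per-patient fit report table.

    Each row dict carries patient_id, group, a FitResult under "fit", a
    response label under "response_type", and "rank" ("best"/"alternate").
    Parameter estimates get one column each plus ``_lo``/``_hi`` columns
    for any profiled intervals.
    """
    records = []
    for row in rows:
        fit = row["fit"]
        rec: dict = {
            "patient_id": row["patient_id"],
            "group": row.get("group", ""),
            "rank": row.get("rank", "best"),
            "model": fit.tag,
            "response_type": row.get("response_type", ""),
            "n_obs": fit.n_obs,
            "n_free": fit.n_free,
            "logL": fit.logL,
            "sigma": fit.sigma,
            "delta_percent": fit.delta_percent,
            "converged": fit.converged,
            "fixed_Td": fit.fixed_Td,
            "rec_start": fit.rec_window[0] if fit.rec_window else None,
            "rec_end": fit.rec_window[1] if fit.rec_window else None,
        }
        for name in _REPORT_PARAMS:
            rec[name] = fit.params.get(name)
        for name, ci in fit.ci.items():
            rec[f"{name}_lo"] = ci.low
            rec[f"{name}_hi"] = ci.high
        records.append(rec)
    return pd.DataFrame(records)


def write_report(rows: list[dict], path) -> pd.DataFrame:
    frame = report_frame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return frame
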