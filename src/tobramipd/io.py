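"""Course file I/O: long-format CSV (and a JSON mirror) for TDM courses.

One row per event, discriminated by ``record_type``:

* ``dose`` — time_h, amount_mg, infusion_h
* ``obs`` — time_h, conc_mg_L, obs_role
* ``covariate`` — timepoint (start/end), age_y, sex, weight_kg, scr_umol_L

plus ``patient_id`` / ``course_id`` on every row. Dose rows also carry the
course-level ``initial dose`` implicitly (the first dose event's amount);
the physician's post-TDM dose, when present, is the amount of the first dose
row flagged ``accepted`` in the optional ``dose_tag`` column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import Observation
from .cohort import CourseRecord
from .pk import CovariateSet, DoseEvent, Regimen

__all__ = ["COURSE_CSV_COLUMNS", "courses_to_frame", "frame_to_courses",
           "write_courses_csv", "read_courses_csv",
           "write_courses_json", "read_courses_json"]

COURSE_CSV_COLUMNS = [
    "patient_id", "course_id", "record_type", "time_h", "amount_mg",
    "infusion_h", "conc_mg_L", "obs_role", "age_y", "sex", "weight_kg",
    "scr_umol_L", "timepoint", "dose_tag",
]


def courses_to_frame(courses: Sequence[CourseRecord]) -> pd.DataFrame:
    """Serialize course records to the long-format event table."""
    rows = []
    for c in courses:
        base = {"patient_id": c.patient_id, "course_id": c.course_id}
        cov = c.covariates_start
        rows.append({**base, "record_type": "covariate", "timepoint": "start",
                     "age_y": cov.age, "sex": cov.sex, "weight_kg": cov.body_weight,
                     "scr_umol_L": cov.serum_creatinine})
        if c.covariates_end is not None:
            cov = c.covariates_end
            rows.append({**base, "record_type": "covariate", "timepoint": "end",
                         "age_y": cov.age, "sex": cov.sex, "weight_kg": cov.body_weight,
                         "scr_umol_L": cov.serum_creatinine})
        for ev in c.regimen.events:
            rows.append({**base, "record_type": "dose", "time_h": ev.start_time,
                         "amount_mg": ev.amount, "infusion_h": ev.infusion_duration})
        if c.accepted_dose is not None:
            rows.append({**base, "record_type": "dose", "time_h": np.nan,
                         "amount_mg": c.accepted_dose, "infusion_h": 0.5,
                         "dose_tag": "accepted"})
        for o in c.observations:
            rows.append({**base, "record_type": "obs", "time_h": o.time,
                         "conc_mg_L": o.concentration, "obs_role": o.role})
    frame = pd.DataFrame(rows)
    for col in COURSE_CSV_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[COURSE_CSV_COLUMNS]


def frame_to_courses(frame: pd.DataFrame) -> list[CourseRecord]:
    """Parse the long-format event table back into course records."""
    required = {"patient_id", "course_id", "record_type"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"course table missing columns: {sorted(missing)}")
    courses = []
    for (pid, cid), grp in frame.groupby(["patient_id", "course_id"], sort=False):
        cov_rows = grp[grp.record_type == "covariate"]
        start_rows = cov_rows[cov_rows.timepoint == "start"]
        if len(start_rows) != 1:
            raise ValueError(f"course {cid}: exactly one start covariate row required")
        s = start_rows.iloc[0]
        cov_start = CovariateSet(age=float(s.age_y), sex=str(s.sex),
                                 body_weight=float(s.weight_kg),
                                 serum_creatinine=float(s.scr_umol_L))
        cov_end = None
        end_rows = cov_rows[cov_rows.timepoint == "end"]
        if len(end_rows) == 1 and not pd.isna(end_rows.iloc[0].scr_umol_L):
            e = end_rows.iloc[0]
            cov_end = CovariateSet(age=float(e.age_y), sex=str(e.sex),
                                   body_weight=float(e.weight_kg),
                                   serum_creatinine=float(e.scr_umol_L))

        dose_rows = grp[grp.record_type == "dose"]
        has_tag = "dose_tag" in grp.columns
        accepted = None
        events = []
        for _, d in dose_rows.iterrows():
            if has_tag and isinstance(d.get("dose_tag"), str) and d.dose_tag == "accepted":
                accepted = float(d.amount_mg)
                continue
            events.append(DoseEvent(start_time=float(d.time_h),
                                    infusion_duration=float(d.infusion_h),
                                    amount=float(d.amount_mg)))
        if not events:
            raise ValueError(f"course {cid}: no dose events")
        events.sort(key=lambda e: e.start_time)
        regimen = Regimen(events=tuple(events))

        obs = [
            Observation(time=float(o.time_h), concentration=float(o.conc_mg_L),
                        role=str(o.obs_role) if isinstance(o.obs_role, str) else "other")
            for _, o in grp[grp.record_type == "obs"].iterrows()
        ]
        obs.sort(key=lambda o: o.time)
        courses.append(CourseRecord(
            patient_id=str(pid), course_id=str(cid),
            covariates_start=cov_start, covariates_end=cov_end,
            regimen=regimen, observations=obs,
            initial_dose=events[0].amount, accepted_dose=accepted,
        ))
    return courses


def write_courses_csv(courses: Sequence[CourseRecord], path: str | Path) -> None:
    courses_to_frame(courses).to_csv(path, index=False)


def read_courses_csv(path: str | Path) -> list[CourseRecord]:
    return frame_to_courses(pd.read_csv(path, float_precision="round_trip"))


def write_courses_json(courses: Sequence[CourseRecord], path: str | Path) -> None:
    """JSON mirror of the CSV dialect (records orient)."""
    frame = courses_to_frame(courses)
    records = json.loads(frame.to_json(orient="records"))
    Path(path).write_text(json.dumps(records, indent=1))


def read_courses_json(path: str | Path) -> list[CourseRecord]:
    records = json.loads(Path(path).read_text())
    return frame_to_courses(pd.DataFrame.from_records(records))
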