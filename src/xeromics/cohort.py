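"""Patients, follow-up visits, and xerostomia end-point construction.

Toxicity (CTCAE dry-mouth grade 0-3) is recorded at irregular follow-up
visits.  Two end-point constructions are supported:

* **time-specific** — three windows after radiotherapy, (0, 6], (6, 15] and
  (15, 24] months (early / late / long-term).  Grades of a patient's visits
  inside a window are averaged (arithmetic mean, half-up rounding) and the
  event is grade >= 2.  Patients without a visit in a window are excluded
  from that end point.
* **longitudinal** — every visit is a separate observation labelled by its
  own grade, with the visit time carried as a model covariate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Patient",
    "FollowUp",
    "Cohort",
    "EndpointDataset",
    "TIME_WINDOWS",
    "EVENT_GRADE",
    "aggregate_window",
    "binarize",
    "build_time_specific",
    "build_longitudinal",
]

#: Time-specific windows in months, half-open (lo, hi].
TIME_WINDOWS: dict[str, tuple[float, float]] = {
    "early": (0.0, 6.0),
    "late": (6.0, 15.0),
    "long-term": (15.0, 24.0),
}

#: Moderate-to-severe xerostomia: CTCAE grade >= 2.
EVENT_GRADE = 2

VALID_GRADES = (0, 1, 2, 3)


@dataclass(frozen=True)
class FollowUp:
    """One toxicity evaluation: months after radiotherapy and CTCAE grade."""

    time: float
    grade: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"follow-up time must be >= 0, got {self.time}")
        if self.grade not in VALID_GRADES:
            raise ValueError(f"grade must be in {VALID_GRADES}, got {self.grade}")


@dataclass
class Patient:
    id: str
    age: float
    sex: str  # 'female' | 'male'
    followups: list[FollowUp] = field(default_factory=list)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass
class Cohort:
    """A list of patients with unique ids."""

    patients: list[Patient]

    def __post_init__(self):
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @classmethod
    def from_tables(cls, patients: pd.DataFrame, followups: pd.DataFrame) -> "Cohort":
        """Build a cohort from the two delimited input tables.

        ``patients`` needs columns ``id, age, sex``; ``followups`` needs
        ``id, time_months, grade``.
        """
        for col in ("id", "age", "sex"):
            if col not in patients.columns:
                raise ValueError(f"patients table is missing column {col!r}")
        for col in ("id", "time_months", "grade"):
            if col not in followups.columns:
                raise ValueError(f"followups table is missing column {col!r}")
        by_id = {
            str(pid): sub.sort_values("time_months")
            for pid, sub in followups.groupby("id")
        }
        plist = []
        for _, row in patients.iterrows():
            fu = [
                FollowUp(float(r.time_months), int(r.grade))
                for r in by_id.get(str(row["id"]), pd.DataFrame()).itertuples()
            ]
            plist.append(Patient(str(row["id"]), float(row["age"]), str(row["sex"]), fu))
        return cls(plist)

    @classmethod
    def read_csv(cls, patients_path, followups_path) -> "Cohort":
        return cls.from_tables(pd.read_csv(patients_path), pd.read_csv(followups_path))

    def write_csv(self, patients_path, followups_path) -> None:
        pd.DataFrame(
            [{"id": p.id, "age": p.age, "sex": p.sex} for p in self.patients]
        ).to_csv(patients_path, index=False)
        rows = [
            {"id": p.id, "time_months": f.time, "grade": f.grade}
            for p in self.patients
            for f in p.followups
        ]
        pd.DataFrame(rows, columns=["id", "time_months", "grade"]).to_csv(
            followups_path, index=False
        )


@dataclass
class EndpointDataset:
    """Binary labels for one end point.

    ``rows`` has columns ``patient_id, label`` plus ``time_months`` for the
    longitudinal end point (one row per visit there, at most one row per
    patient otherwise).
    """

    endpoint: str  # 'early' | 'late' | 'long-term' | 'longitudinal'
    rows: pd.DataFrame
    window: tuple[float, float] | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.rows["label"].to_numpy(dtype=int)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.rows["patient_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.rows)


def aggregate_window(
    followups: list[FollowUp], window: tuple[float, float]
) -> int | None:
    """Window grade: mean of in-window grades, rounded half-up; None if empty.

    The window is half-open (lo, hi]: a visit exactly at the lower bound
    belongs to the previous window.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"invalid window {window}")
    grades = [f.grade for f in followups if lo < f.time <= hi]
    if not grades:
        return None
    return int(math.floor(np.mean(grades) + 0.5))


def binarize(grade: int) -> int:
    """1 iff the grade is moderate-to-severe (>= 2)."""
    if grade not in VALID_GRADES:
        raise ValueError(f"grade must be in {VALID_GRADES}, got {grade}")
    return int(grade >= EVENT_GRADE)


def build_time_specific(cohort: Cohort) -> dict[str, EndpointDataset]:
    """Derive the early/late/long-term binary end-point datasets."""
    out = {}
    for name, window in TIME_WINDOWS.items():
        rows = []
        for p in cohort:
            if not p.followups:
                warnings.warn(f"patient {p.id} has no follow-ups; excluded")
                continue
            g = aggregate_window(p.followups, window)
            if g is None:
                continue
            rows.append({"patient_id": p.id, "label": binarize(g)})
        out[name] = EndpointDataset(
            endpoint=name,
            rows=pd.DataFrame(rows, columns=["patient_id", "label"]),
            window=window,
        )
    return out


def build_longitudinal(cohort: Cohort) -> EndpointDataset:
    """One observation per follow-up visit, labelled by that visit's grade.

    The visit time (months) is kept as a covariate column so longitudinal
    models can use it as a predictor; no grades are averaged.
    """
    rows = []
    for p in cohort:
        if not p.followups:
            warnings.warn(f"patient {p.id} has no follow-ups; excluded")
            continue
        for f in p.followups:
            rows.append(
                {
                    "patient_id": p.id,
                    "time_months": f.time,
                    "label": binarize(f.grade),
                }
            )
    return EndpointDataset(
        endpoint="longitudinal",
        rows=pd.DataFrame(rows, columns=["patient_id", "time_months", "label"]),
    )
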