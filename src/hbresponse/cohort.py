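"""In-memory cohort data model, CSV I/O, and the embedded study-cohort fixture.

The unit of analysis is a patient undergoing neoadjuvant chemotherapy (NAC)
whose tumor vascularity is tracked by ultrasound-guided near-infrared imaging.
Each patient carries receptor-subtype flags (HER2, ER, triple-negative),
histologic grading (Nottingham score, mitotic count) and a Miller-Payne
pathologic response grade; each imaging visit contributes maximum total /
oxygenated / deoxygenated hemoglobin concentrations over the tumor region.

Responder status is the Miller-Payne dichotomy used throughout the analysis:
grades 4-5 (near-complete or complete pathologic response) versus grades 1-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "REGIMENS",
    "concat_cohorts",
    "PatientRecord",
    "TimepointMeasurement",
    "CohortTable",
    "CohortParseError",
    "dichotomize_response",
    "code_predictors",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_fixture_table1",
    "design_frame",
]

#: Imaging visit labels, in chronological order.
TIMEPOINTS = (
    "baseline",
    "day7",
    "cycle1",
    "cycle2",
    "cycle3",
    "cycle5",
    "presurgery",
)

#: Treatment regimen labels as used in the study cohort.
REGIMENS = ("ACT", "TPT", "TPT&FEC", "TC", "Carbo/T", "other")

PATIENT_COLUMNS = (
    "patient_id",
    "age",
    "her2",
    "er",
    "tn",
    "nottingham_score",
    "mitotic_count",
    "miller_payne",
    "regimen",
)

MEASUREMENT_COLUMNS = (
    "patient_id",
    "timepoint",
    "tHb_max",
    "oxyHb_max",
    "deoxyHb_max",
    "replicate_maxima",
    "us_largest_dim",
)


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the schema; names the offending row."""


def dichotomize_response(miller_payne: int) -> int:
    """Dichotomize a Miller-Payne grade into responder (1) vs non-responder (0).

    Grades 4 and 5 — a marked (>90%) disappearance of tumor cells or no
    identifiable malignant cells — count as response; grades 1-3 do not.

    Parameters
    ----------
    miller_payne : int
        Miller-Payne grade in 1..5.

    Returns
    -------
    int
        1 if ``miller_payne >= 4`` else 0.
    """
    grade = int(miller_payne)
    if not 1 <= grade <= 5:
        raise ValueError(f"Miller-Payne grade must be in 1..5, got {miller_payne!r}")
    return 1 if grade >= 4 else 0


@dataclass(frozen=True)
class PatientRecord:
    """One subject: subtype flags, histology, and pathologic response.

    ``responder`` is always derived from ``miller_payne`` (grades 4-5 → 1) and
    is recomputed on construction; it cannot disagree with the grade.
    """

    patient_id: str
    age: int
    her2: int
    er: int
    tn: int
    nottingham_score: int
    mitotic_count: int
    miller_payne: int
    regimen: str = "other"
    responder: int = field(default=-1)

    def __post_init__(self) -> None:
        for name in ("her2", "er", "tn"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1 for patient {self.patient_id}")
        if self.tn == 1 and (self.her2 == 1 or self.er == 1):
            raise ValueError(
                f"patient {self.patient_id}: triple-negative requires her2=0 and er=0"
            )
        if not 3 <= self.nottingham_score <= 9:
            raise ValueError(
                f"patient {self.patient_id}: Nottingham score must be in 3..9"
            )
        if self.mitotic_count < 0:
            raise ValueError(f"patient {self.patient_id}: mitotic count must be >= 0")
        if self.regimen not in REGIMENS:
            raise ValueError(
                f"patient {self.patient_id}: unknown regimen {self.regimen!r}"
            )
        derived = dichotomize_response(self.miller_payne)
        if self.responder not in (-1, derived):
            raise ValueError(
                f"patient {self.patient_id}: responder flag inconsistent with "
                f"Miller-Payne grade {self.miller_payne}"
            )
        object.__setattr__(self, "responder", derived)

    @property
    def subtype(self) -> str:
        """Clinical subtype bucket: 'HER2+', 'ER+/HER2-', or 'TN'."""
        if self.tn:
            return "TN"
        if self.her2:
            return "HER2+"
        return "ER+/HER2-"


def code_predictors(record: PatientRecord) -> dict[str, int]:
    """Code the subtype flags for modelling.

    The coding is oriented so that 1 marks the level with increased probability
    of pathologic complete response: TN=1 for triple-negative, HER2=1 for
    HER2-positive, and ER_code=0 for ER-positive / 1 for ER-negative.
    """
    return {"TN": record.tn, "HER2": record.her2, "ER_code": 0 if record.er else 1}


@dataclass(frozen=True)
class TimepointMeasurement:
    """Per-visit maximum hemoglobin values (μmol/L) for one patient.

    ``tHb_max`` is the average of the 5-10 quality replicate maxima retained
    after motion exclusion; when ``replicate_maxima`` is present it must equal
    their arithmetic mean to numerical tolerance.
    """

    patient_id: str
    timepoint: str
    tHb_max: float
    oxyHb_max: float
    deoxyHb_max: float
    replicate_maxima: tuple[float, ...] = ()
    us_largest_dim: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r} for patient {self.patient_id}"
            )
        for name in ("tHb_max", "oxyHb_max", "deoxyHb_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for patient {self.patient_id}")
        object.__setattr__(self, "replicate_maxima", tuple(self.replicate_maxima))
        if self.replicate_maxima:
            mean = sum(self.replicate_maxima) / len(self.replicate_maxima)
            if not math.isclose(mean, self.tHb_max, rel_tol=1e-6, abs_tol=1e-6):
                raise ValueError(
                    f"patient {self.patient_id} @ {self.timepoint}: tHb_max "
                    f"{self.tHb_max} != mean of replicates {mean}"
                )
        if self.us_largest_dim is not None and self.us_largest_dim < 0:
            raise ValueError(
                f"us_largest_dim must be >= 0 for patient {self.patient_id}"
            )


@dataclass
class CohortTable:
    """A cohort: patient records plus their longitudinal measurements."""

    patients: list[PatientRecord]
    measurements: list[TimepointMeasurement] = field(default_factory=list)
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.provenance not in ("fixture", "synthetic", "user"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")
        known = set(ids)
        seen: set[tuple[str, str]] = set()
        for m in self.measurements:
            if m.patient_id not in known:
                raise ValueError(f"measurement references unknown patient {m.patient_id!r}")
            key = (m.patient_id, m.timepoint)
            if key in seen:
                raise ValueError(f"duplicate measurement for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def measurement(self, patient_id: str, timepoint: str) -> TimepointMeasurement | None:
        for m in self.measurements:
            if m.patient_id == patient_id and m.timepoint == timepoint:
                return m
        return None

    def patients_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "her2": p.her2,
                "er": p.er,
                "tn": p.tn,
                "nottingham_score": p.nottingham_score,
                "mitotic_count": p.mitotic_count,
                "miller_payne": p.miller_payne,
                "regimen": p.regimen,
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows, columns=list(PATIENT_COLUMNS))

    def measurements_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": m.patient_id,
                "timepoint": m.timepoint,
                "tHb_max": m.tHb_max,
                "oxyHb_max": m.oxyHb_max,
                "deoxyHb_max": m.deoxyHb_max,
                "replicate_maxima": ";".join(repr(v) for v in m.replicate_maxima),
                "us_largest_dim": m.us_largest_dim,
            }
            for m in self.measurements
        ]
        return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def write_cohort_csv(table: CohortTable, patients_path, measurements_path) -> None:
    """Write a cohort to a pair of long-format CSV files."""
    table.patients_frame().to_csv(patients_path, index=False)
    table.measurements_frame().to_csv(measurements_path, index=False)


def _parse_replicates(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return ()
    return tuple(float(v) for v in str(cell).split(";") if v != "")


def read_cohort_csv(patients_path, measurements_path=None, provenance: str = "user") -> CohortTable:
    """Read a cohort from CSV; ``measurements_path`` may be omitted or empty.

    Raises :class:`CohortParseError` naming the offending row on schema
    violations (missing columns, duplicate patient/timepoint pairs, or
    measurements whose patient_id does not resolve).
    """
    pdf = pd.read_csv(patients_path)
    missing = set(PATIENT_COLUMNS) - set(pdf.columns)
    if missing:
        raise CohortParseError(f"{patients_path}: missing columns {sorted(missing)}")
    patients = []
    for i, row in pdf.iterrows():
        try:
            patients.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    age=int(row["age"]),
                    her2=int(row["her2"]),
                    er=int(row["er"]),
                    tn=int(row["tn"]),
                    nottingham_score=int(row["nottingham_score"]),
                    mitotic_count=int(row["mitotic_count"]),
                    miller_payne=int(row["miller_payne"]),
                    regimen=str(row["regimen"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CohortParseError(f"{patients_path} row {i + 2}: {exc}") from exc

    measurements: list[TimepointMeasurement] = []
    if measurements_path is not None and Path(measurements_path).exists():
        mdf = pd.read_csv(measurements_path)
        missing = set(MEASUREMENT_COLUMNS) - set(mdf.columns)
        if missing:
            raise CohortParseError(
                f"{measurements_path}: missing columns {sorted(missing)}"
            )
        for i, row in mdf.iterrows():
            try:
                us = row["us_largest_dim"]
                measurements.append(
                    TimepointMeasurement(
                        patient_id=str(row["patient_id"]),
                        timepoint=str(row["timepoint"]),
                        tHb_max=float(row["tHb_max"]),
                        oxyHb_max=float(row["oxyHb_max"]),
                        deoxyHb_max=float(row["deoxyHb_max"]),
                        replicate_maxima=_parse_replicates(row["replicate_maxima"]),
                        us_largest_dim=None if pd.isna(us) else float(us),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise CohortParseError(
                    f"{measurements_path} row {i + 2}: {exc}"
                ) from exc
    try:
        return CohortTable(patients, measurements, provenance=provenance)
    except ValueError as exc:
        raise CohortParseError(str(exc)) from exc


# --------------------------------------------------------------------------
# Study-cohort fixture: the 22 patients of the new cohort, as printed.
# Columns: age, NS, mitotic count /10 HPF, tn, her2, er, Miller-Payne, regimen.
# ER weak positives are coded ER-positive. Hemoglobin values are not printed
# and are therefore absent.
_TABLE1 = (
    (59, 6, 2, 0, 0, 1, 3, "ACT"),
    (55, 6, 1, 0, 0, 1, 4, "ACT"),
    (33, 4, 2, 0, 0, 1, 3, "ACT"),
    (61, 6, 1, 1, 0, 0, 1, "ACT"),
    (59, 6, 5, 0, 0, 1, 2, "ACT"),
    (68, 6, 3, 0, 0, 1, 3, "ACT"),
    (51, 9, 40, 1, 0, 0, 5, "ACT"),
    (53, 9, 62, 1, 0, 0, 3, "ACT"),
    (51, 7, 15, 0, 1, 1, 5, "TPT"),
    (74, 8, 8, 0, 1, 0, 5, "TPT"),
    (57, 9, 16, 0, 1, 0, 4, "TPT&FEC"),
    (51, 9, 14, 0, 1, 0, 5, "TPT"),
    (59, 7, 1, 0, 1, 1, 5, "TPT"),
    (61, 4, 3, 0, 1, 1, 5, "TPT"),
    (37, 8, 9, 0, 1, 1, 4, "TPT"),
    (54, 8, 20, 0, 1, 1, 5, "TPT"),
    (40, 8, 15, 0, 1, 1, 5, "TPT"),
    (62, 9, 12, 0, 1, 1, 3, "TPT"),
    (37, 8, 42, 0, 1, 1, 5, "TPT"),
    (72, 9, 42, 0, 0, 1, 3, "TC"),
    (57, 9, 14, 1, 0, 0, 5, "Carbo/T"),
    (41, 9, 8, 1, 0, 0, 3, "Carbo/T"),
)


def load_fixture_table1() -> CohortTable:
    """The 22-patient study cohort (subtypes, histology, response grades).

    Hemoglobin measurements are not part of the published record and are not
    included; pair this fixture with the synthetic generator when longitudinal
    biomarkers are needed.
    """
    patients = [
        PatientRecord(
            patient_id=f"P{i + 1:02d}",
            age=age,
            her2=her2,
            er=er,
            tn=tn,
            nottingham_score=ns,
            mitotic_count=mc,
            miller_payne=mp,
            regimen=reg,
        )
        for i, (age, ns, mc, tn, her2, er, mp, reg) in enumerate(_TABLE1)
    ]
    return CohortTable(patients, [], provenance="fixture")


def concat_cohorts(*tables: CohortTable, provenance: str = "user") -> CohortTable:
    """Combine cohorts (e.g. an earlier training cohort and a new one).

    Patient ids must be globally unique across the inputs.
    """
    patients = [p for t in tables for p in t.patients]
    measurements = [m for t in tables for m in t.measurements]
    return CohortTable(patients, measurements, provenance=provenance)


#: Predictor names available from :func:`design_frame`.
DESIGN_COLUMNS = (
    "HER2",
    "ER_code",
    "TN",
    "NS",
    "MC",
    "tHb",
    "oxyHb",
    "deoxyHb",
    "pct_tHb_day7",
    "pct_tHb_cyc1",
    "pct_tHb_cyc2",
    "pct_tHb_cyc3",
    "pct_tHb_cyc5",
    "pct_tHb_presurgery",
)

_PCT_TIMEPOINT = {
    "pct_tHb_day7": "day7",
    "pct_tHb_cyc1": "cycle1",
    "pct_tHb_cyc2": "cycle2",
    "pct_tHb_cyc3": "cycle3",
    "pct_tHb_cyc5": "cycle5",
    "pct_tHb_presurgery": "presurgery",
}


def design_frame(cohort: CohortTable) -> pd.DataFrame:
    """Per-patient modelling table: coded predictors, biomarkers, and outcome.

    Columns are the subtype codings (HER2, ER_code, TN), histology (NS, MC),
    the baseline hemoglobin maxima (tHb, oxyHb, deoxyHb in μmol/L), and the
    baseline-normalized %tHb at each follow-up visit (``pct_tHb_*``, percent).
    ``responder`` holds the Miller-Payne dichotomy, ``miller_payne`` the raw
    grade. Visits a patient did not attend yield NaN.
    """
    from .hemoglobin import percent_tHb

    by_key = {(m.patient_id, m.timepoint): m for m in cohort.measurements}
    rows = []
    for p in cohort.patients:
        row: dict[str, object] = {"patient_id": p.patient_id}
        row.update(code_predictors(p))
        row["NS"] = p.nottingham_score
        row["MC"] = p.mitotic_count
        base = by_key.get((p.patient_id, "baseline"))
        row["tHb"] = base.tHb_max if base else float("nan")
        row["oxyHb"] = base.oxyHb_max if base else float("nan")
        row["deoxyHb"] = base.deoxyHb_max if base else float("nan")
        for col, tp in _PCT_TIMEPOINT.items():
            m = by_key.get((p.patient_id, tp))
            if base is not None and base.tHb_max > 0 and m is not None:
                row[col] = percent_tHb(base.tHb_max, m.tHb_max)
            else:
                row[col] = float("nan")
        row["miller_payne"] = p.miller_payne
        row["responder"] = p.responder
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
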