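"""Flat-table EMR extract model: schemas, validation, readers and writers.

A cohort bundle is a directory of six UTF-8 CSV files (RFC-4180 quoting):

    patients.csv      patient_id, sex, birth_date, birth_weight_z, birth_length_z
    observations.csv  patient_id, date, kind, value
    labs.csv          patient_id, date, result_id, analyte, value, context
    diagnoses.csv     patient_id, date, icd10_code, source
    medications.csv   patient_id, start_date, end_date, drug_class
    staging.csv       patient_id, date, kind, value

Dates are ISO-8601 calendar dates (chart data are day-resolution). All
downstream modules consume the validated :class:`Cohort` container.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

OBSERVATION_KINDS = {"height_cm", "weight_kg"}
LAB_ANALYTES = {"igf1", "gh_peak"}
LAB_CONTEXTS = {"basal", "stimulation_clonidine", "stimulation_arginine",
                "on_gh_treatment_flag"}
DIAGNOSIS_SOURCES = {"visit_diagnosis", "problem_list"}
DRUG_CLASSES = {"gh_therapy", "systemic_glucocorticoid", "other"}
STAGING_KINDS = {"tanner_stage", "bone_age_months"}

# Physiologic sanity bounds for anthropometry.
HEIGHT_BOUNDS_CM = (30.0, 220.0)
WEIGHT_BOUNDS_KG = (1.0, 250.0)

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[A-Za-z0-9]+)?$")

TABLE_COLUMNS = {
    "patients": ["patient_id", "sex", "birth_date", "birth_weight_z",
                 "birth_length_z"],
    "observations": ["patient_id", "date", "kind", "value"],
    "labs": ["patient_id", "date", "result_id", "analyte", "value", "context"],
    "diagnoses": ["patient_id", "date", "icd10_code", "source"],
    "medications": ["patient_id", "start_date", "end_date", "drug_class"],
    "staging": ["patient_id", "date", "kind", "value"],
}


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    row: int  # 0-based data-row index in the source table
    message: str

    def __str__(self) -> str:
        return f"{self.table}[row {self.row}]: {self.message}"


class CohortValidationError(ValueError):
    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        preview = "\n".join(str(i) for i in issues[:20])
        more = f"\n... and {len(issues) - 20} more" if len(issues) > 20 else ""
        super().__init__(f"{len(issues)} validation failure(s):\n{preview}{more}")


@dataclass
class Cohort:
    """Validated in-memory EMR extract."""

    patients: pd.DataFrame
    observations: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    staging: pd.DataFrame
    issues: list[ValidationIssue] = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def for_patient(self, table: str, patient_id: str) -> pd.DataFrame:
        frame = self.table(table)
        return frame[frame["patient_id"] == patient_id]


def icd10_valid(code: str) -> bool:
    return bool(ICD10_PATTERN.match(code))


def code_matches(code: str, prefix: str) -> bool:
    """Prefix match after dot-stripping: prefix 'E03' matches 'E03.9'."""
    return code.replace(".", "").startswith(prefix.replace(".", ""))


def medication_active(start_date: date, end_date: date | None, on: date) -> bool:
    """Interval semantics: start <= d <= end, open-ended when end is absent."""
    if on < start_date:
        return False
    return end_date is None or on <= end_date


def _parse_date(value, issues, table, row, column) -> date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return date.fromisoformat(str(value))
    except ValueError:
        issues.append(ValidationIssue(table, row, f"{column}: bad date {value!r}"))
        return None


def _to_float(value) -> float | None:
    """Parse a float field; None when empty or unparseable."""
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _is_empty(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value == ""


def _check_columns(name: str, frame: pd.DataFrame) -> None:
    expected = TABLE_COLUMNS[name]
    if list(frame.columns) != expected:
        raise ValueError(
            f"{name}: expected columns {expected}, found {list(frame.columns)}")


def validate_cohort(raw: dict[str, pd.DataFrame]
                    ) -> tuple[Cohort, list[ValidationIssue]]:
    """Enforce all row-level invariants; returns (cohort, issues).

    Offending rows are dropped from the returned tables; the caller decides
    whether any issue is fatal (strict mode).
    """
    issues: list[ValidationIssue] = []
    for name, frame in raw.items():
        _check_columns(name, frame)

    pat = raw["patients"].copy()
    keep = []
    birth_by_pid: dict[str, date] = {}
    seen: set[str] = set()
    for i, row in pat.iterrows():
        ok = True
        pid = str(row["patient_id"])
        if pid in seen:
            issues.append(ValidationIssue("patients", i, f"duplicate patient_id {pid}"))
            ok = False
        try:
            from .growth_reference import Sex
            Sex(row["sex"])
        except ValueError:
            issues.append(ValidationIssue("patients", i, f"bad sex {row['sex']!r}"))
            ok = False
        bd = _parse_date(row["birth_date"], issues, "patients", i, "birth_date")
        if bd is None:
            ok = False
        for col in ("birth_weight_z", "birth_length_z"):
            if not _is_empty(row[col]) and _to_float(row[col]) is None:
                issues.append(ValidationIssue(
                    "patients", i, f"{col}: bad number {row[col]!r}"))
                ok = False
        if ok:
            seen.add(pid)
            birth_by_pid[pid] = bd
        keep.append(ok)
    pat = pat[pd.Series(keep, index=pat.index, dtype=bool)].reset_index(drop=True)
    pat["birth_date"] = pat["birth_date"].map(lambda v: date.fromisoformat(str(v)))
    for col in ("birth_weight_z", "birth_length_z"):
        pat[col] = pat[col].map(_to_float)

    def _events(name: str, frame: pd.DataFrame, date_cols: list[str],
                row_check) -> pd.DataFrame:
        out_keep = []
        frame = frame.copy()
        parsed_dates: dict[str, list] = {c: [] for c in date_cols}
        for i, row in frame.iterrows():
            ok = True
            pid = str(row["patient_id"])
            if pid not in birth_by_pid:
                issues.append(ValidationIssue(name, i, f"unknown patient_id {pid}"))
                ok = False
            dates_here = {}
            for c in date_cols:
                d = _parse_date(row[c], issues, name, i, c)
                dates_here[c] = d
                required = not (name == "medications" and c == "end_date")
                if d is None and required:
                    ok = False
            if ok:
                anchor = dates_here.get("date") or dates_here.get("start_date")
                if anchor is not None and anchor < birth_by_pid[pid]:
                    issues.append(ValidationIssue(
                        name, i, f"event date {anchor} precedes birth"))
                    ok = False
            if ok:
                msg = row_check(row, dates_here)
                if msg:
                    issues.append(ValidationIssue(name, i, msg))
                    ok = False
            out_keep.append(ok)
            for c in date_cols:
                parsed_dates[c].append(dates_here[c])
        for c in date_cols:
            frame[c] = parsed_dates[c]
        return frame[pd.Series(out_keep, index=frame.index,
                               dtype=bool)].reset_index(drop=True)

    def obs_check(row, _dates):
        if row["kind"] not in OBSERVATION_KINDS:
            return f"bad observation kind {row['kind']!r}"
        v = _to_float(row["value"])
        if v is None or v <= 0:
            return f"non-positive or missing value {row['value']!r}"
        lo, hi = HEIGHT_BOUNDS_CM if row["kind"] == "height_cm" else WEIGHT_BOUNDS_KG
        if not (lo < v < hi):
            return f"{row['kind']} value {v} outside sanity bounds ({lo}, {hi})"
        return None

    def lab_check(row, _dates):
        if row["analyte"] not in LAB_ANALYTES:
            return f"bad analyte {row['analyte']!r}"
        if row["context"] not in LAB_CONTEXTS:
            return f"bad context {row['context']!r}"
        v = _to_float(row["value"])
        if v is None or v < 0:
            return f"negative or missing value {row['value']!r}"
        if row["analyte"] == "gh_peak" and not str(row["context"]).startswith(
                "stimulation"):
            return "gh_peak requires a stimulation context"
        return None

    def dx_check(row, _dates):
        if not icd10_valid(str(row["icd10_code"])):
            return f"lexically invalid ICD-10 code {row['icd10_code']!r}"
        if row["source"] not in DIAGNOSIS_SOURCES:
            return f"bad source {row['source']!r}"
        return None

    def med_check(row, dates):
        if row["drug_class"] not in DRUG_CLASSES:
            return f"bad drug_class {row['drug_class']!r}"
        start, end = dates.get("start_date"), dates.get("end_date")
        if start and end and end < start:
            return f"end_date {end} precedes start_date {start}"
        return None

    def stage_check(row, _dates):
        if row["kind"] not in STAGING_KINDS:
            return f"bad staging kind {row['kind']!r}"
        v = _to_float(row["value"])
        if v is None:
            return "missing value"
        if row["kind"] == "tanner_stage" and (v not in {1, 2, 3, 4, 5}):
            return f"Tanner stage must be 1-5, got {v}"
        if row["kind"] == "bone_age_months" and v < 0:
            return f"negative bone age {v}"
        return None

    obs = _events("observations", raw["observations"], ["date"], obs_check)
    labs = _events("labs", raw["labs"], ["date"], lab_check)
    dx = _events("diagnoses", raw["diagnoses"], ["date"], dx_check)
    meds = _events("medications", raw["medications"], ["start_date", "end_date"],
                   med_check)
    stg = _events("staging", raw["staging"], ["date"], stage_check)

    for frame in (obs, labs, stg):
        if not frame.empty:
            frame["value"] = frame["value"].astype(float)
    if not labs.empty:
        labs["result_id"] = labs["result_id"].astype(str)
    meds["end_date"] = meds["end_date"].map(lambda d: d if isinstance(d, date) else None)

    cohort = Cohort(patients=pat, observations=obs, labs=labs, diagnoses=dx,
                    medications=meds, staging=stg, issues=issues)
    return cohort, issues


def read_cohort(path: str | Path, *, strict: bool = True) -> Cohort:
    """Read and validate a cohort bundle directory.

    In strict mode any invariant breach aborts with row coordinates; otherwise
    offending rows are dropped and recorded on ``cohort.issues``.
    """
    path = Path(path)
    raw: dict[str, pd.DataFrame] = {}
    for name in TABLE_COLUMNS:
        file = path / f"{name}.csv"
        if not file.exists():
            raise FileNotFoundError(f"missing table file {file}")
        raw[name] = pd.read_csv(file, dtype=str, keep_default_na=False,
                                na_values=[""])
    cohort, issues = validate_cohort(raw)
    if strict and issues:
        raise CohortValidationError(issues)
    return cohort


_SORT_KEYS = {
    "patients": ["patient_id"],
    "observations": ["patient_id", "date", "kind"],
    "labs": ["patient_id", "date", "result_id"],
    "diagnoses": ["patient_id", "date", "icd10_code"],
    "medications": ["patient_id", "start_date", "drug_class"],
    "staging": ["patient_id", "date", "kind"],
}


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort bundle with deterministic column order and row sort."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, columns in TABLE_COLUMNS.items():
        frame = cohort.table(name).copy()
        if frame.empty:
            frame = pd.DataFrame(columns=columns)
        frame = frame.loc[:, columns]
        frame = frame.sort_values(_SORT_KEYS[name], kind="mergesort")
        out = frame.map(
            lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v))
            else (v.isoformat() if isinstance(v, date) else v))
        out.to_csv(path / f"{name}.csv", index=False, lineterminator="\n")
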