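"""Case-finding funnel: short stature, low IGF-1, temporal linkage, exclusions.

The funnel narrows a whole-clinic cohort in four nested steps:

1. any height-for-age z-score at or below the short-stature cutoff (-3.0 SDS);
2. at least one IGF-1 result below the assay-specific 2.5th percentile, the
   earliest such result becoming the patient's *index*;
3. a qualifying short-stature height recorded within one year (±365 days,
   inclusive) of the index low IGF-1;
4. no secondary cause of IGF-1 deficiency: no diagnosis code in any of the
   configured ICD-10 prefix sets (visit diagnoses or problem list, any date)
   and no BMI below the 5th percentile at the encounter nearest the index.

Survivors become :class:`CandidateCase` objects and are labelled with the
abnormal-growth categories used in pediatric short-stature workups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd
from scipy.stats import norm

from . import longitudinal_review as lr
from .ehr_model import Cohort, code_matches, medication_active
from .growth_reference import (
    GrowthReferenceTable,
    MeasureKind,
    ZScoreResult,
    age_in_months,
    paired_bmi,
)
from .igf1_reference import (
    DEFAULT_IGF1_CALENDAR,
    AssayCalendar,
    IGF1Classification,
    IGF1ReferenceTable,
    classify_patient_igf1,
    first_low_igf1,
)

#: Editable default ICD-10 prefix sets for secondary causes of low IGF-1.
#: Institutional code lists vary; these are starting points, not a standard.
DEFAULT_CODE_SETS: dict[str, tuple[str, ...]] = {
    "malnutrition": ("E40", "E41", "E42", "E43", "E44", "E45", "E46",
                     "R63.4", "R63.6"),
    "hypothyroidism": ("E00", "E01", "E02", "E03"),
    "gh_deficiency": ("E23.0",),
    "hypopituitarism": ("E23.0", "E23.6", "E89.3"),
    "liver_disease": ("K70", "K71", "K72", "K73", "K74", "K75", "K76", "K77"),
    "other": (),
}

#: Default code prefixes feeding the endocrine / genetic growth categories.
DEFAULT_CATEGORY_CODE_SETS: dict[str, tuple[str, ...]] = {
    # constitutional delay of growth and puberty, septo-optic dysplasia
    "endocrine_disease": ("E30.0", "E34.3", "Q04.4"),
    # chromosomal anomalies, congenital malformation syndromes, muscular dystrophy
    "genetic_disorder": ("Q87", "Q9", "G71.0", "Q77", "Q78"),
}

GROWTH_CATEGORIES = (
    "transient_pubertal_slowing",
    "endocrine_disease",
    "small_for_gestational_age",
    "genetic_disorder",
    "idiopathic_short_stature",
    "medication_adverse_effect",
)

#: BMI z equivalent of the 5th percentile.
BMI_5TH_PCTL_Z = float(norm.ppf(0.05))


@dataclass(frozen=True)
class QualifyingHeight:
    on_date: date
    value_cm: float
    z: float


@dataclass(frozen=True)
class CandidateCase:
    """A patient surviving steps 1-4, with linkage metadata."""

    patient_id: str
    index_igf1: IGF1Classification
    linked_height_date: date
    height_z_at_link: float
    categories: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ExclusionEvent:
    patient_id: str
    step: str
    rule: str
    detail: str


@dataclass
class FunnelResult:
    """Nested per-step retained sets plus linkage metadata and logs."""

    step_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    qualifying_heights: dict[str, list[QualifyingHeight]] = field(default_factory=dict)
    index_igf1: dict[str, IGF1Classification] = field(default_factory=dict)
    linked_height: dict[str, QualifyingHeight] = field(default_factory=dict)
    candidates: list[CandidateCase] = field(default_factory=list)
    exclusions: list[ExclusionEvent] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {step: len(ids) for step, ids in self.step_sets.items()}

    def check_nesting(self) -> bool:
        order = ["step1", "step2", "step3", "step4"]
        present = [s for s in order if s in self.step_sets]
        return all(self.step_sets[b] <= self.step_sets[a]
                   for a, b in zip(present, present[1:]))


def step1_short_stature(cohort: Cohort,
                        growth_tables: dict[MeasureKind, GrowthReferenceTable],
                        *, threshold_z: float = -3.0,
                        inclusive: bool = True,
                        ) -> tuple[dict[str, list[QualifyingHeight]], list[str]]:
    """Patients with any height-for-age z at (or below) the cutoff.

    Returns (qualifying heights per retained patient, skipped-observation log).
    Observations whose age falls outside the reference grid are logged and
    skipped, never silently classified.
    """
    table = growth_tables[MeasureKind.HEIGHT_FOR_AGE]
    info = cohort.patients.set_index("patient_id")
    heights = cohort.observations[cohort.observations["kind"] == "height_cm"]
    qualifying: dict[str, list[QualifyingHeight]] = {}
    skipped: list[str] = []
    for _, row in heights.iterrows():
        pid = row["patient_id"]
        patient = info.loc[pid]
        age = age_in_months(patient["birth_date"], row["date"])
        try:
            res: ZScoreResult = table.zscore(patient["sex"], age, row["value"])
        except Exception as exc:
            skipped.append(f"{pid}@{row['date']}: {exc}")
            continue
        hit = res.z <= threshold_z if inclusive else res.z < threshold_z
        if hit:
            qualifying.setdefault(pid, []).append(
                QualifyingHeight(row["date"], float(row["value"]), res.z))
    return qualifying, skipped


def step2_low_igf1(step1_ids: frozenset[str], cohort: Cohort,
                   refs: IGF1ReferenceTable,
                   calendar: AssayCalendar = DEFAULT_IGF1_CALENDAR,
                   *, staging_window_days: int = 365,
                   ) -> tuple[dict[str, IGF1Classification],
                              dict[str, list[IGF1Classification]]]:
    """First low IGF-1 per step-1 patient; also returns the full series.

    The index result is the first recorded instance of a low value.
    """
    info = cohort.patients.set_index("patient_id")
    index: dict[str, IGF1Classification] = {}
    series: dict[str, list[IGF1Classification]] = {}
    for pid in sorted(step1_ids):
        patient = info.loc[pid]
        classifications = classify_patient_igf1(
            cohort.for_patient("labs", pid),
            cohort.for_patient("staging", pid),
            patient_id=pid, sex=patient["sex"],
            birth_date=patient["birth_date"], refs=refs, calendar=calendar,
            staging_window_days=staging_window_days)
        series[pid] = classifications
        first = first_low_igf1(classifications)
        if first is not None:
            index[pid] = first
    return index, series


def step3_temporal_link(qualifying: dict[str, list[QualifyingHeight]],
                        index: dict[str, IGF1Classification],
                        *, window_days: int = 365,
                        ) -> dict[str, QualifyingHeight]:
    """Link each indexed patient to a qualifying height within the window.

    The linked height is the qualifying observation closest in time to the
    index low IGF-1 (|gap| <= window_days, symmetric and inclusive); the
    earlier observation wins ties.
    """
    linked: dict[str, QualifyingHeight] = {}
    for pid, idx in index.items():
        best: QualifyingHeight | None = None
        best_gap: int | None = None
        for qh in sorted(qualifying.get(pid, []), key=lambda q: q.on_date):
            gap = abs((qh.on_date - idx.collection_date).days)
            if gap > window_days:
                continue
            if best is None or gap < best_gap:
                best, best_gap = qh, gap
        if best is not None:
            linked[pid] = best
    return linked


def step4_exclude_secondary(linked: dict[str, QualifyingHeight],
                            index: dict[str, IGF1Classification],
                            cohort: Cohort,
                            growth_tables: dict[MeasureKind, GrowthReferenceTable],
                            code_sets: dict[str, tuple[str, ...]] | None = None,
                            *, bmi_percentile: float = 5.0,
                            bmi_pairing_window_days: int = 0,
                            ) -> tuple[list[CandidateCase], list[ExclusionEvent]]:
    """Drop patients with a coded secondary cause or a malnutrition-range BMI.

    Diagnoses from either source and any date count (problem lists are
    cumulative). BMI is evaluated at the encounter nearest the index date.
    """
    code_sets = DEFAULT_CODE_SETS if code_sets is None else code_sets
    bmi_table = growth_tables[MeasureKind.BMI_FOR_AGE]
    info = cohort.patients.set_index("patient_id")
    candidates: list[CandidateCase] = []
    exclusions: list[ExclusionEvent] = []
    for pid in sorted(linked):
        excluded = False
        dx = cohort.for_patient("diagnoses", pid)
        for _, row in dx.iterrows():
            for set_name, prefixes in code_sets.items():
                hit = next((p for p in prefixes
                            if code_matches(row["icd10_code"], p)), None)
                if hit is not None:
                    exclusions.append(ExclusionEvent(
                        pid, "step4", f"code_set:{set_name}",
                        f"{row['icd10_code']} ({row['source']}, {row['date']}) "
                        f"matches prefix {hit}"))
                    excluded = True
                    break
            if excluded:
                break
        if not excluded:
            patient = info.loc[pid]
            bmis = paired_bmi(cohort.for_patient("observations", pid),
                              window_days=bmi_pairing_window_days)
            if not bmis.empty:
                gaps = (bmis["date"] - index[pid].collection_date).map(
                    lambda d: abs(d.days))
                nearest = bmis.loc[gaps[gaps == gaps.min()].index[0]]
                try:
                    res = bmi_table.zscore(
                        patient["sex"],
                        age_in_months(patient["birth_date"], nearest["date"]),
                        nearest["bmi"])
                except Exception:
                    res = None
                if res is not None and res.percentile < bmi_percentile:
                    exclusions.append(ExclusionEvent(
                        pid, "step4", "bmi_below_5th_percentile",
                        f"BMI {nearest['bmi']:.1f} kg/m^2 on {nearest['date']} "
                        f"= {res.percentile:.1f}th percentile (z {res.z:+.2f})"))
                    excluded = True
        if not excluded:
            candidates.append(CandidateCase(
                patient_id=pid, index_igf1=index[pid],
                linked_height_date=linked[pid].on_date,
                height_z_at_link=linked[pid].z))
    return candidates, exclusions


def classify_growth_category(candidate: CandidateCase, cohort: Cohort,
                             growth_tables: dict[MeasureKind, GrowthReferenceTable],
                             category_code_sets: dict[str, tuple[str, ...]] | None = None,
                             ) -> frozenset[str]:
    """Multi-label abnormal-growth categorisation of a candidate.

    Labels may overlap; idiopathic short stature is the residual label when
    height is at or below -2 SDS and nothing else fired.
    """
    sets = (DEFAULT_CATEGORY_CODE_SETS if category_code_sets is None
            else category_code_sets)
    pid = candidate.patient_id
    patient = cohort.patients.set_index("patient_id").loc[pid]
    labels: set[str] = set()

    for col in ("birth_weight_z", "birth_length_z"):
        v = patient[col]
        if v is not None and not pd.isna(v) and v <= -2.0:
            labels.add("small_for_gestational_age")

    meds = cohort.for_patient("medications", pid)
    gluco = meds[meds["drug_class"] == "systemic_glucocorticoid"]
    for _, row in gluco.iterrows():
        if medication_active(row["start_date"], row["end_date"],
                             candidate.index_igf1.collection_date):
            labels.add("medication_adverse_effect")

    dx = cohort.for_patient("diagnoses", pid)
    for _, row in dx.iterrows():
        for label, prefixes in sets.items():
            if any(code_matches(row["icd10_code"], p) for p in prefixes):
                labels.add(label)

    # Transient pubertal slowing: growth normalized off GH and a pubertal
    # (Tanner >= 2) staging read exists at or before the last height.
    table = growth_tables[MeasureKind.HEIGHT_FOR_AGE]
    heights = cohort.for_patient("observations", pid)
    heights = heights[heights["kind"] == "height_cm"]
    z_series = []
    for _, row in heights.iterrows():
        try:
            res = table.zscore(patient["sex"],
                               age_in_months(patient["birth_date"], row["date"]),
                               row["value"])
        except Exception:
            continue
        z_series.append((row["date"], res.z))
    gh_meds = meds[meds["drug_class"] == "gh_therapy"]
    exposures = [(row["start_date"], row["end_date"])
                 for _, row in gh_meds.iterrows()]
    normalized, _ = lr.growth_normalization(z_series, exposures)
    staging = cohort.for_patient("staging", pid)
    pubertal = staging[(staging["kind"] == "tanner_stage")
                       & (staging["value"] >= 2)]
    if normalized and not pubertal.empty and z_series:
        last_height_date = max(d for d, _ in z_series)
        if (pubertal["date"] <= last_height_date).any():
            labels.add("transient_pubertal_slowing")

    if not labels and candidate.height_z_at_link <= -2.0:
        labels.add("idiopathic_short_stature")
    return frozenset(labels)


def run_case_finding(cohort: Cohort,
                     growth_tables: dict[MeasureKind, GrowthReferenceTable],
                     igf1_refs: IGF1ReferenceTable,
                     calendar: AssayCalendar = DEFAULT_IGF1_CALENDAR,
                     code_sets: dict[str, tuple[str, ...]] | None = None,
                     category_code_sets: dict[str, tuple[str, ...]] | None = None,
                     *, threshold_z: float = -3.0, inclusive: bool = True,
                     link_window_days: int = 365, bmi_percentile: float = 5.0,
                     staging_window_days: int = 365,
                     ) -> tuple[FunnelResult, dict[str, list[IGF1Classification]]]:
    """Run funnel steps 1-4 and categorise the surviving candidates."""
    funnel = FunnelResult()
    qualifying, skipped = step1_short_stature(
        cohort, growth_tables, threshold_z=threshold_z, inclusive=inclusive)
    funnel.qualifying_heights = qualifying
    funnel.skipped = skipped
    funnel.step_sets["step1"] = frozenset(qualifying)

    index, series = step2_low_igf1(
        funnel.step_sets["step1"], cohort, igf1_refs, calendar,
        staging_window_days=staging_window_days)
    funnel.index_igf1 = index
    funnel.step_sets["step2"] = frozenset(index)

    linked = step3_temporal_link(qualifying, index, window_days=link_window_days)
    funnel.linked_height = linked
    funnel.step_sets["step3"] = frozenset(linked)

    candidates, exclusions = step4_exclude_secondary(
        linked, index, cohort, growth_tables, code_sets,
        bmi_percentile=bmi_percentile)
    funnel.exclusions = exclusions
    funnel.candidates = [
        CandidateCase(
            patient_id=c.patient_id, index_igf1=c.index_igf1,
            linked_height_date=c.linked_height_date,
            height_z_at_link=c.height_z_at_link,
            categories=classify_growth_category(
                c, cohort, growth_tables, category_code_sets))
        for c in candidates]
    funnel.step_sets["step4"] = frozenset(c.patient_id for c in candidates)
    assert funnel.check_nesting()
    return funnel, series
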