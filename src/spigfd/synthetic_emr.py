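"""Seeded synthetic EMR cohorts with known ground truth, plus packaged fixtures.

No patient-level data from the motivating cohort are available, so every
pipeline stage is exercised against generated records. The generator emulates
a pediatric tertiary-care clinic over the 2013-2021 study window with six
patient archetypes:

``normal_stature``
    heights around the median, normal IGF-1 (screened out at step 1);
``short_stature_only``
    persistently at or below -3 SDS but normal IGF-1 (out at step 2);
``secondary_cause``
    short with low IGF-1 plus a coded secondary cause or malnutrition-range
    BMI (out at step 4); subtypes: malnutrition code, malnutrition BMI,
    hypothyroidism, GH deficiency, liver disease;
``constitutional_delay_normalizer``
    low IGF-1 at entry that normalizes spontaneously at a log-normally
    sampled time (median 10.8 months, truncated to 6.1-24.1 months) with
    height recovery above -2 SDS (excluded at step 6, spontaneous-both);
``gh_responder``
    started on GH therapy, with on-treatment height gain above 0.5 SDS per
    12 months and IGF-1 normalization on therapy (excluded at step 6,
    GH-related);
``true_spigfd``
    height drifting within [-4.5, -3.1] SDS, IGF-1 always low, GH-sufficient
    or untested, no exclusion codes — the archetype the pipeline must keep.

Toy LMS growth tables and IGF-1 reference bounds are generated alongside the
cohort so every threshold is exactly known; algorithm correctness is thereby
separated from reference-table fidelity.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ehr_model import TABLE_COLUMNS, Cohort
from .growth_reference import (
    DAYS_PER_MONTH,
    GrowthReferenceTable,
    MeasureKind,
    Sex,
)
from .igf1_reference import (
    DEFAULT_GH_CALENDAR,
    DEFAULT_IGF1_CALENDAR,
    GH_PEAK_THRESHOLDS,
    AssayCalendar,
    IGF1ReferenceTable,
    Stratifier,
)

ARCHETYPES = ("normal_stature", "short_stature_only", "secondary_cause",
              "constitutional_delay_normalizer", "gh_responder", "true_spigfd")

SECONDARY_SUBTYPES = ("malnutrition_code", "malnutrition_bmi",
                      "hypothyroidism", "gh_deficiency", "liver_disease")

_SUBTYPE_CODES = {
    "malnutrition_code": "E43",
    "hypothyroidism": "E03.9",
    "gh_deficiency": "E23.0",
    "liver_disease": "K72.9",
}

_BENIGN_CODES = ("J06.9", "H52.1", "L20.9", "Z00.1")


# ---------------------------------------------------------------------------
# Toy reference tables
# ---------------------------------------------------------------------------

_HEIGHT_ANCHORS = {
    "male": [(0, 50.0), (12, 75.0), (24, 87.0), (60, 110.0), (120, 138.0),
             (168, 163.0), (228, 176.0)],
    "female": [(0, 49.0), (12, 74.0), (24, 86.0), (60, 109.0), (120, 138.0),
               (168, 160.0), (228, 163.0)],
}
_WEIGHT_ANCHORS = {
    "male": [(0, 3.4), (12, 10.0), (24, 12.5), (60, 18.5), (120, 32.0),
             (168, 54.0), (228, 68.0)],
    "female": [(0, 3.3), (12, 9.5), (24, 12.0), (60, 18.0), (120, 32.0),
               (168, 50.0), (228, 59.0)],
}
_BMI_ANCHORS = {
    "male": [(0, 13.5), (12, 17.0), (24, 16.3), (60, 15.3), (120, 16.9),
             (168, 20.3), (228, 22.3)],
    "female": [(0, 13.3), (12, 16.7), (24, 16.0), (60, 15.2), (120, 17.0),
               (168, 20.3), (228, 21.8)],
}
_LMS_SHAPE = {  # (L, S) per measure; exercises power and near-log branches
    MeasureKind.HEIGHT_FOR_AGE: (1.0, 0.04),
    MeasureKind.WEIGHT_FOR_AGE: (-0.2, 0.13),
    MeasureKind.BMI_FOR_AGE: (-1.0, 0.10),
}


def toy_growth_tables(grid_step_months: float = 6.0
                      ) -> dict[MeasureKind, GrowthReferenceTable]:
    """Smooth synthetic LMS grids covering ages 0-228 months, both sexes."""
    anchors = {MeasureKind.HEIGHT_FOR_AGE: _HEIGHT_ANCHORS,
               MeasureKind.WEIGHT_FOR_AGE: _WEIGHT_ANCHORS,
               MeasureKind.BMI_FOR_AGE: _BMI_ANCHORS}
    grid = np.arange(0.0, 228.0 + 1e-9, grid_step_months)
    tables = {}
    for kind, per_sex in anchors.items():
        L, S = _LMS_SHAPE[kind]
        rows = []
        for sex, pts in per_sex.items():
            xs = [a for a, _ in pts]
            ys = [m for _, m in pts]
            for age in grid:
                rows.append({"sex": sex, "age_months": float(age), "L": L,
                             "M": float(np.interp(age, xs, ys)), "S": S})
        tables[kind] = GrowthReferenceTable(kind, pd.DataFrame(rows))
    return tables


_IGF1_AGE_BANDS = [  # (lo, hi, p2_5 male, p2_5 female) in months / ug/L
    (0, 36, 20.0, 22.0),
    (36, 72, 35.0, 38.0),
    (72, 108, 52.0, 55.0),
    (108, 144, 72.0, 76.0),
    (144, 180, 92.0, 96.0),
    (180, 240, 102.0, 106.0),
]
_IGF1_TANNER = [(1, 25.0, 27.0), (2, 60.0, 63.0), (3, 95.0, 99.0),
                (4, 105.0, 109.0), (5, 100.0, 104.0)]


def toy_igf1_reference() -> IGF1ReferenceTable:
    """Synthetic 2.5th-percentile bounds for both assay eras and all stratifiers.

    The newer assay reads about 5% higher than the older one, mimicking a
    vendor switch without cross-calibration.
    """
    rows = []
    for assay, scale in (("IDS-iSYS", 1.0), ("Liaison", 1.05)):
        for lo, hi, m, f in _IGF1_AGE_BANDS:
            for strat in (Stratifier.CHRONOLOGICAL_AGE, Stratifier.BONE_AGE):
                rows.append({"assay": assay, "sex": "male",
                             "stratifier": strat.value, "stratum_lo": lo,
                             "stratum_hi": hi, "p2_5": round(m * scale, 1)})
                rows.append({"assay": assay, "sex": "female",
                             "stratifier": strat.value, "stratum_lo": lo,
                             "stratum_hi": hi, "p2_5": round(f * scale, 1)})
        for stage, m, f in _IGF1_TANNER:
            rows.append({"assay": assay, "sex": "male",
                         "stratifier": Stratifier.TANNER_STAGE.value,
                         "stratum_lo": stage, "stratum_hi": stage,
                         "p2_5": round(m * scale, 1)})
            rows.append({"assay": assay, "sex": "female",
                         "stratifier": Stratifier.TANNER_STAGE.value,
                         "stratum_lo": stage, "stratum_hi": stage,
                         "p2_5": round(f * scale, 1)})
    return IGF1ReferenceTable(pd.DataFrame(rows))


@dataclass
class ReferenceBundle:
    growth_tables: dict[MeasureKind, GrowthReferenceTable]
    igf1_refs: IGF1ReferenceTable
    igf1_calendar: AssayCalendar = DEFAULT_IGF1_CALENDAR
    gh_calendar: AssayCalendar = DEFAULT_GH_CALENDAR


def toy_reference_bundle() -> ReferenceBundle:
    return ReferenceBundle(growth_tables=toy_growth_tables(),
                           igf1_refs=toy_igf1_reference())


# ---------------------------------------------------------------------------
# Cohort specification and generation
# ---------------------------------------------------------------------------

class CohortSpec(BaseModel):
    """Generator configuration; the seed fixes all downstream randomness."""

    n_patients: int = Field(ge=1, default=200)
    seed: int = 0
    proportions: dict[str, float] = Field(default_factory=lambda: {
        "normal_stature": 0.40,
        "short_stature_only": 0.25,
        "secondary_cause": 0.15,
        "constitutional_delay_normalizer": 0.08,
        "gh_responder": 0.07,
        "true_spigfd": 0.05,
    })
    #: spontaneous IGF-1 normalization timing (months): log-normal by median
    #: and log-SD, truncated to the observed clinical range
    normalization_median_months: float = 10.8
    normalization_log_sd: float = 0.35
    normalization_range_months: tuple[float, float] = (6.1, 24.1)
    height_noise_cm: float = 0.3
    igf1_noise_ugl: float = 1.0
    visit_interval_months: float = 6.0
    n_visits: int = Field(ge=2, default=10)
    entry_window: tuple[date, date] = (date(2014, 1, 1), date(2016, 6, 30))
    entry_age_months: tuple[float, float] = (24.0, 144.0)

    @model_validator(mode="after")
    def _check(self):
        unknown = set(self.proportions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("archetype proportions must be non-negative")
        return self


def _archetype_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so planted counts are exact."""
    quotas = {a: proportions.get(a, 0.0) * n for a in ARCHETYPES}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(ARCHETYPES, key=lambda a: (-(quotas[a] - counts[a]), a))
    for a in by_rem[:short]:
        counts[a] += 1
    return counts


def _tanner_from_age(age_months: float) -> int:
    if age_months < 120:
        return 1
    if age_months < 144:
        return 2
    if age_months < 162:
        return 3
    if age_months < 180:
        return 4
    return 5


@dataclass
class GeneratedCohort:
    cohort: Cohort
    ground_truth: pd.DataFrame  # patient_id, archetype, subtype, expected_outcome
    references: ReferenceBundle


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Generate a cohort bundle, its ground-truth labels and toy references."""
    rng = np.random.default_rng(spec.seed)
    refs = toy_reference_bundle()
    height_t = refs.growth_tables[MeasureKind.HEIGHT_FOR_AGE]
    bmi_t = refs.growth_tables[MeasureKind.BMI_FOR_AGE]
    frame = refs.igf1_refs.frame
    low_igf1 = 0.5 * float(frame["p2_5"].min())
    normal_igf1 = 1.5 * float(frame["p2_5"].max())

    counts = _archetype_counts(spec.proportions, spec.n_patients)
    archetypes: list[str] = []
    for a in ARCHETYPES:
        archetypes.extend([a] * counts[a])
    rng.shuffle(archetypes)

    patients, observations, labs, diagnoses, medications, staging = \
        [], [], [], [], [], []
    truth = []
    entry_lo, entry_hi = spec.entry_window
    entry_span = (entry_hi - entry_lo).days

    for i, archetype in enumerate(archetypes):
        pid = f"P{i:04d}"
        sex = Sex.MALE.value if rng.random() < 0.5 else Sex.FEMALE.value
        entry = entry_lo + timedelta(days=int(rng.integers(0, entry_span + 1)))
        age0 = float(rng.uniform(*spec.entry_age_months))
        birth = entry - timedelta(days=round(age0 * DAYS_PER_MONTH))
        subtype = ""

        visit_offsets = [round(k * spec.visit_interval_months * DAYS_PER_MONTH
                               + (rng.integers(-15, 16) if k else 0))
                         for k in range(spec.n_visits)]
        visits = [entry + timedelta(days=d) for d in visit_offsets]
        visit_months = [d / DAYS_PER_MONTH for d in visit_offsets]

        # archetype-specific trajectory parameters
        bmi_target = 0.0
        igf_low_until = None  # months; None = never low, inf = always low
        gh_start = None
        expected = None
        if archetype == "normal_stature":
            z_path = [float(rng.uniform(-1.5, 1.5))] * spec.n_visits
            expected = "excluded_step1"
        elif archetype == "short_stature_only":
            z0 = float(rng.uniform(-3.8, -3.2))
            z_path = [z0] * spec.n_visits
            expected = "excluded_step2"
        elif archetype == "secondary_cause":
            subtype = SECONDARY_SUBTYPES[rng.integers(len(SECONDARY_SUBTYPES))]
            z0 = float(rng.uniform(-3.8, -3.2))
            z_path = [z0] * spec.n_visits
            igf_low_until = math.inf
            expected = "excluded_step4"
            if subtype == "malnutrition_bmi":
                bmi_target = -2.6
            else:
                code_date = visits[int(rng.integers(spec.n_visits))]
                source = ("problem_list" if rng.random() < 0.5
                          else "visit_diagnosis")
                diagnoses.append((pid, code_date, _SUBTYPE_CODES[subtype], source))
            if subtype == "gh_deficiency":
                test_date = visits[1]
                analyzer = refs.gh_calendar.assay_for_date(test_date)
                peak = max(0.2, GH_PEAK_THRESHOLDS[analyzer]
                           - float(rng.uniform(1.0, 3.0)))
                labs.append((pid, test_date, f"{pid}-S0", "gh_peak", peak,
                             "stimulation_clonidine"))
        elif archetype == "constitutional_delay_normalizer":
            t_norm = float(np.exp(np.log(spec.normalization_median_months)
                                  + spec.normalization_log_sd * rng.standard_normal()))
            t_norm = float(np.clip(t_norm, *spec.normalization_range_months))
            igf_low_until = t_norm
            z_path = [(-3.3 if m < 6 else
                       min(-1.5, -3.3 + 1.8 * (m - 6) / 24.0))
                      for m in visit_months]
            expected = "excluded_spont_both"
        elif archetype == "gh_responder":
            gh_start = entry + timedelta(days=90)
            igf_low_until = 4.0  # normalizes once on therapy
            z_path = [(-3.4 if m < 3 else
                       min(-1.2, -3.4 + 0.9 * (m - 3) / 12.0))
                      for m in visit_months]
            expected = "excluded_gh_response"
        else:  # true_spigfd
            z0 = float(rng.uniform(-4.0, -3.4))
            drift = float(rng.uniform(-0.10, 0.05))  # SDS per year
            z_path = [float(np.clip(z0 + drift * m / 12.0, -4.5, -3.1))
                      for m in visit_months]
            igf_low_until = math.inf
            expected = "spigfd_candidate"
            if rng.random() < 0.5:
                test_date = visits[2]
                analyzer = refs.gh_calendar.assay_for_date(test_date)
                peak = GH_PEAK_THRESHOLDS[analyzer] + float(rng.uniform(1.0, 6.0))
                labs.append((pid, test_date, f"{pid}-S0", "gh_peak", peak,
                             "stimulation_clonidine"))

        patients.append((pid, sex, birth,
                         float(np.clip(rng.normal(0.0, 0.5), -1.8, 1.8)),
                         float(np.clip(rng.normal(0.0, 0.5), -1.8, 1.8))))
        truth.append({"patient_id": pid, "archetype": archetype,
                      "subtype": subtype, "expected_outcome": expected})

        has_staging = rng.random() < 0.3
        for k, (vdate, month) in enumerate(zip(visits, visit_months)):
            age = age0 + month
            height = height_t.value_at(sex, age, z_path[k]) \
                + float(rng.normal(0.0, spec.height_noise_cm))
            bmi = bmi_t.value_at(sex, age,
                                 bmi_target + float(rng.normal(0.0, 0.2)))
            weight = bmi * (height / 100.0) ** 2
            observations.append((pid, vdate, "height_cm", round(height, 1)))
            observations.append((pid, vdate, "weight_kg", round(weight, 2)))
            if igf_low_until is None:
                value = normal_igf1
            elif month < igf_low_until:
                value = low_igf1
            else:
                value = normal_igf1
            value = max(0.5, value + float(rng.normal(0.0, spec.igf1_noise_ugl)))
            labs.append((pid, vdate, f"{pid}-L{k}", "igf1", round(value, 1),
                         "basal"))
            if has_staging and age >= 96:
                staging.append((pid, vdate, "tanner_stage",
                                float(_tanner_from_age(age))))
                if rng.random() < 0.5:
                    staging.append((pid, vdate, "bone_age_months",
                                    round(age + float(rng.normal(0.0, 6.0)), 1)))
        if gh_start is not None:
            medications.append((pid, gh_start, None, "gh_therapy"))
        if archetype in ("normal_stature", "short_stature_only") \
                and rng.random() < 0.4:
            diagnoses.append((pid, visits[int(rng.integers(spec.n_visits))],
                              _BENIGN_CODES[rng.integers(len(_BENIGN_CODES))],
                              "visit_diagnosis"))

    cohort = Cohort(
        patients=pd.DataFrame(patients, columns=TABLE_COLUMNS["patients"]),
        observations=pd.DataFrame(observations,
                                  columns=TABLE_COLUMNS["observations"]),
        labs=pd.DataFrame(labs, columns=TABLE_COLUMNS["labs"]),
        diagnoses=pd.DataFrame(diagnoses, columns=TABLE_COLUMNS["diagnoses"]),
        medications=pd.DataFrame(medications,
                                 columns=TABLE_COLUMNS["medications"]),
        staging=pd.DataFrame(staging, columns=TABLE_COLUMNS["staging"]),
    )
    ground_truth = pd.DataFrame(truth)
    return GeneratedCohort(cohort=cohort, ground_truth=ground_truth,
                           references=refs)


# ---------------------------------------------------------------------------
# Packaged fixtures replaying the published funnel and case table
# ---------------------------------------------------------------------------

#: Published per-step retained counts of the motivating study's funnel.
FUNNEL_FIXTURE: dict[str, int] = {
    "step1_short_stature": 4863,
    "step2_low_igf1": 233,
    "step3_temporal_link": 124,
    "step4_potential_spigfd": 30,
    "step6_reviewed": 11,
}


def case_table_fixture() -> pd.DataFrame:
    """The 11 chart-reviewed case summaries, as packaged data."""
    with importlib.resources.files("spigfd.data").joinpath(
            "case_review_table.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype=str)


def published_fixtures() -> tuple[dict[str, int], pd.DataFrame]:
    """(funnel-count fixture, case-review table fixture)."""
    return dict(FUNNEL_FIXTURE), case_table_fixture()
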