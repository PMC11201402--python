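from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from spigfd.case_finding import run_case_finding
from spigfd.growth_reference import GrowthReferenceTable, MeasureKind
from spigfd.igf1_reference import IGF1ReferenceTable
from spigfd.synthetic_emr import CohortSpec, ReferenceBundle, generate_cohort

from conftest import make_cohort, patient

BIRTH = date(2008, 1, 1)


def flat_table(kind, M, S=0.0625, L=1.0):
    rows = [{"sex": sex, "age_months": a, "L": L, "M": M, "S": S}
            for sex in ("male", "female") for a in (0.0, 240.0)]
    return GrowthReferenceTable(kind, pd.DataFrame(rows))


@pytest.fixture(scope="module")
def flat_refs():
    """Age-constant references with exactly representable LMS arithmetic."""
    growth = {
        MeasureKind.HEIGHT_FOR_AGE: flat_table(MeasureKind.HEIGHT_FOR_AGE, 100.0),
        MeasureKind.WEIGHT_FOR_AGE: flat_table(MeasureKind.WEIGHT_FOR_AGE, 20.0),
        MeasureKind.BMI_FOR_AGE: flat_table(MeasureKind.BMI_FOR_AGE, 16.0),
    }
    igf = IGF1ReferenceTable(pd.DataFrame(
        [{"assay": a, "sex": s, "stratifier": "chronological_age",
          "stratum_lo": 0, "stratum_hi": 240, "p2_5": 50.0}
         for a in ("IDS-iSYS", "Liaison") for s in ("male", "female")]))
    return ReferenceBundle(growth_tables=growth, igf1_refs=igf)


def height_for_z(z):
    # M=100, S=0.0625 (dyadic) keeps the z computation exact in binary
    return 100.0 * (1.0 + 0.0625 * z)


def run_funnel(cohort, refs, **kw):
    return run_case_finding(cohort, refs.growth_tables, refs.igf1_refs, **kw)


class TestStepBoundaries:
    def _one_patient(self, z, igf_value=10.0, extra_obs=(), diagnoses=None):
        day = date(2015, 6, 1)
        obs = [("P1", day, "height_cm", height_for_z(z))] + list(extra_obs)
        labs = [("P1", day, "r1", "igf1", igf_value, "basal")]
        return make_cohort(patients=[patient("P1", birth=BIRTH)],
                           observations=obs, labs=labs, diagnoses=diagnoses)

    def test_z_exactly_minus3_included(self, flat_refs):
        funnel, _ = run_funnel(self._one_patient(-3.0), flat_refs)
        assert funnel.step_sets["step1"] == {"P1"}

    def test_z_minus29_excluded(self, flat_refs):
        funnel, _ = run_funnel(self._one_patient(-2.9), flat_refs)
        assert funnel.step_sets["step1"] == frozenset()

    def test_igf1_exactly_at_bound_not_low(self, flat_refs):
        funnel, _ = run_funnel(self._one_patient(-3.5, igf_value=50.0), flat_refs)
        assert funnel.step_sets["step1"] == {"P1"}
        assert funnel.step_sets["step2"] == frozenset()

    @pytest.mark.parametrize("gap_days,linked", [(152, True), (365, True),
                                                 (366, False), (400, False)])
    def test_one_year_window_inclusive(self, flat_refs, gap_days, linked):
        h_day = date(2015, 6, 1)
        cohort = make_cohort(
            patients=[patient("P1", birth=BIRTH)],
            observations=[("P1", h_day, "height_cm", height_for_z(-3.5))],
            labs=[("P1", h_day + timedelta(days=gap_days), "r1", "igf1",
                   10.0, "basal")])
        funnel, _ = run_funnel(cohort, flat_refs)
        assert (funnel.step_sets["step3"] == {"P1"}) is linked

    def test_closest_height_wins_earlier_on_tie(self, flat_refs):
        idx = date(2015, 6, 1)
        early, late = idx - timedelta(days=30), idx + timedelta(days=30)
        cohort = make_cohort(
            patients=[patient("P1", birth=BIRTH)],
            observations=[("P1", early, "height_cm", height_for_z(-3.2)),
                          ("P1", late, "height_cm", height_for_z(-3.4))],
            labs=[("P1", idx, "r1", "igf1", 10.0, "basal")])
        funnel, _ = run_funnel(cohort, flat_refs)
        assert funnel.linked_height["P1"].on_date == early


class TestStep4Exclusions:
    def _cohort(self, *, bmi_z=None, code=None):
        day = date(2015, 6, 1)
        height = height_for_z(-3.5)
        obs = [("P1", day, "height_cm", height)]
        if bmi_z is not None:
            bmi = 16.0 * (1.0 + 0.0625 * bmi_z)
            obs.append(("P1", day, "weight_kg", bmi * (height / 100.0) ** 2))
        dx = [("P1", day, code, "problem_list")] if code else None
        return make_cohort(patients=[patient("P1", birth=BIRTH)],
                           observations=obs,
                           labs=[("P1", day, "r1", "igf1", 10.0, "basal")],
                           diagnoses=dx)

    def test_hypothyroidism_code_excludes(self, flat_refs):
        funnel, _ = run_funnel(self._cohort(code="E03.9"), flat_refs)
        assert funnel.step_sets["step4"] == frozenset()
        assert any(e.rule == "code_set:hypothyroidism" for e in funnel.exclusions)

    def test_low_bmi_excludes(self, flat_refs):
        funnel, _ = run_funnel(self._cohort(bmi_z=-1.7), flat_refs)
        assert funnel.step_sets["step4"] == frozenset()
        assert any(e.rule == "bmi_below_5th_percentile" for e in funnel.exclusions)

    def test_clean_patient_retained(self, flat_refs):
        funnel, _ = run_funnel(self._cohort(bmi_z=0.0), flat_refs)
        assert funnel.step_sets["step4"] == {"P1"}

    def test_exclusion_log_is_sound(self):
        # every logged exclusion names a rule whose predicate re-evaluates
        # true on the raw data
        gen = generate_cohort(CohortSpec(n_patients=80, seed=21))
        funnel, _ = run_funnel(gen.cohort, gen.references)
        from spigfd.case_finding import DEFAULT_CODE_SETS
        from spigfd.ehr_model import code_matches
        assert funnel.exclusions
        for event in funnel.exclusions:
            if event.rule.startswith("code_set:"):
                set_name = event.rule.split(":", 1)[1]
                dx = gen.cohort.for_patient("diagnoses", event.patient_id)
                assert any(
                    code_matches(row["icd10_code"], p)
                    for _, row in dx.iterrows()
                    for p in DEFAULT_CODE_SETS[set_name])
            else:
                assert event.rule == "bmi_below_5th_percentile"
                assert "percentile" in event.detail


class TestGrowthCategories:
    def _base(self, bw_z=None, diagnoses=None):
        day = date(2015, 6, 1)
        return make_cohort(
            patients=[patient("P1", birth=BIRTH, bw_z=bw_z)],
            observations=[("P1", day, "height_cm", height_for_z(-2.5))],
            labs=[("P1", day, "r1", "igf1", 10.0, "basal")],
            diagnoses=diagnoses)

    def test_sga_from_birth_weight(self, flat_refs):
        cohort = self._base(bw_z=-2.5)
        funnel, _ = run_funnel(cohort, flat_refs, threshold_z=-2.0)
        assert "small_for_gestational_age" in funnel.candidates[0].categories

    def test_endocrine_and_genetic_codes_overlap(self, flat_refs):
        day = date(2015, 6, 1)
        cohort = self._base(diagnoses=[("P1", day, "E30.0", "problem_list"),
                                       ("P1", day, "G71.0", "visit_diagnosis")])
        funnel, _ = run_funnel(cohort, flat_refs, threshold_z=-2.0)
        cats = funnel.candidates[0].categories
        assert {"endocrine_disease", "genetic_disorder"} <= cats

    def test_iss_is_residual_label(self, flat_refs):
        funnel, _ = run_funnel(self._base(), flat_refs, threshold_z=-2.0)
        assert funnel.candidates[0].categories == {"idiopathic_short_stature"}


class TestFunnelProperties:
    def test_nesting_holds_on_generated_cohorts(self):
        for seed in (1, 2):
            gen = generate_cohort(CohortSpec(n_patients=60, seed=seed))
            funnel, _ = run_funnel(gen.cohort, gen.references)
            s = funnel.step_sets
            assert s["step4"] <= s["step3"] <= s["step2"] <= s["step1"]

    def test_idempotent_on_own_survivors(self):
        # restricting the cohort to step-4 survivors and re-running keeps
        # every step equal to that survivor set
        gen = generate_cohort(CohortSpec(n_patients=80, seed=5))
        funnel, _ = run_funnel(gen.cohort, gen.references)
        survivors = funnel.step_sets["step4"]
        c = gen.cohort
        sub = type(c)(
            patients=c.patients[c.patients["patient_id"].isin(survivors)],
            observations=c.observations[c.observations["patient_id"].isin(survivors)],
            labs=c.labs[c.labs["patient_id"].isin(survivors)],
            diagnoses=c.diagnoses[c.diagnoses["patient_id"].isin(survivors)],
            medications=c.medications[c.medications["patient_id"].isin(survivors)],
            staging=c.staging[c.staging["patient_id"].isin(survivors)])
        funnel2, _ = run_funnel(sub, gen.references)
        assert all(funnel2.step_sets[k] == survivors
                   for k in ("step1", "step2", "step3", "step4"))


def brute_force_steps(gen):
    """Independent re-derivation of funnel steps 1-3 from the raw tables."""
    cohort, refs = gen.cohort, gen.references
    height_rows = refs.growth_tables[MeasureKind.HEIGHT_FOR_AGE].rows
    igf_frame = refs.igf1_refs.frame
    info = cohort.patients.set_index("patient_id")

    def z_of(pid, day, value):
        p = info.loc[pid]
        age = (day - p["birth_date"]).days / 30.4375
        sub = height_rows[height_rows["sex"] == p["sex"]]
        L = np.interp(age, sub["age_months"], sub["L"])
        M = np.interp(age, sub["age_months"], sub["M"])
        S = np.interp(age, sub["age_months"], sub["S"])
        return ((value / M) ** L - 1.0) / (L * S)

    heights = cohort.observations[cohort.observations["kind"] == "height_cm"]
    qualifying: dict[str, list] = {}
    for _, row in heights.iterrows():
        z = z_of(row["patient_id"], row["date"], row["value"])
        if z <= -3.0:
            qualifying.setdefault(row["patient_id"], []).append(row["date"])
    step1 = set(qualifying)

    index: dict[str, date] = {}
    for pid in step1:
        p = info.loc[pid]
        labs = cohort.for_patient("labs", pid)
        igf = labs[(labs["analyte"] == "igf1") & (labs["context"] == "basal")]
        stg = cohort.for_patient("staging", pid)
        lows = []
        for _, row in igf.iterrows():
            day = row["date"]
            assay = "IDS-iSYS" if day < date(2017, 10, 1) else "Liaison"
            age = (day - p["birth_date"]).days / 30.4375
            threshold = None
            for strat_kind, stage_kind in (("tanner_stage", "tanner_stage"),
                                           ("bone_age", "bone_age_months"),
                                           ("chronological_age", None)):
                if stage_kind is None:
                    datum = age
                else:
                    reads = stg[stg["kind"] == stage_kind].sort_values("date")
                    if reads.empty:
                        continue
                    gaps = (reads["date"] - day).map(lambda d: abs(d.days))
                    if gaps.min() > 365:
                        continue
                    datum = float(reads.loc[gaps[gaps == gaps.min()].index[0],
                                            "value"])
                sub = igf_frame[(igf_frame["assay"] == assay)
                                & (igf_frame["sex"] == p["sex"])
                                & (igf_frame["stratifier"] == strat_kind)]
                if strat_kind == "tanner_stage":
                    sub = sub[sub["stratum_lo"] == datum]
                else:
                    sub = sub[(sub["stratum_lo"] <= datum)
                              & (datum < sub["stratum_hi"])]
                if not sub.empty:
                    threshold = float(sub.iloc[0]["p2_5"])
                    break
            if threshold is not None and row["value"] < threshold:
                lows.append((day, str(row["result_id"])))
        if lows:
            index[pid] = min(lows)[0]

    step3 = {pid for pid, idx_date in index.items()
             if any(abs((d - idx_date).days) <= 365 for d in qualifying[pid])}
    return step1, set(index), step3, index


class TestBruteForceOracle:
    def test_steps_1_to_3_match_exhaustive_scan(self, small_cohort):
        funnel, _ = run_funnel(small_cohort.cohort, small_cohort.references)
        step1, step2, step3, index = brute_force_steps(small_cohort)
        assert funnel.step_sets["step1"] == step1
        assert funnel.step_sets["step2"] == step2
        assert funnel.step_sets["step3"] == step3
        for pid in step2:
            assert funnel.index_igf1[pid].collection_date == index[pid]
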