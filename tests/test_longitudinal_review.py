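import random
from datetime import date, timedelta

import pytest

from spigfd.igf1_reference import IGF1Classification, Stratifier
from spigfd.longitudinal_review import (
    Verdict,
    gh_clinical_response,
    gh_deficiency,
    growth_normalization,
    igf1_normalization,
    parse_response_descriptor,
    review_case_summaries,
    verdict_counts,
    verdict_from_flags,
)
from spigfd.synthetic_emr import case_table_fixture


def cls(rid, day, is_low, value=None):
    return IGF1Classification(
        result_id=rid, patient_id="P1", collection_date=day,
        assay_id="IDS-iSYS", value=10.0 if value is None else value,
        stratifier_used=Stratifier.CHRONOLOGICAL_AGE,
        threshold_applied=50.0, is_low=is_low)


class TestGHDeficiency:
    @pytest.mark.parametrize("day,peak,status", [
        (date(2018, 1, 1), 5.0, "deficient"),    # Dxl era, cutoff 5.4
        (date(2018, 1, 1), 5.4, "sufficient"),   # strict inequality
        (date(2020, 1, 1), 7.0, "deficient"),    # Roche era, cutoff 7.4
        (date(2020, 1, 1), 7.4, "sufficient"),
    ])
    def test_analyzer_specific_cutoffs(self, day, peak, status):
        got, _ = gh_deficiency([(day, peak)])
        assert got == status

    def test_maximum_peak_decides(self):
        got, best = gh_deficiency([(date(2018, 1, 1), 4.0),
                                   (date(2018, 6, 1), 6.0)])
        assert got == "sufficient"
        assert best.peak_gh == 6.0

    def test_no_tests_is_indeterminate(self):
        assert gh_deficiency([]) == ("indeterminate", None)


class TestClinicalResponse:
    def test_half_sd_gain_in_ten_months_on_gh(self):
        t0 = date(2018, 1, 1)
        series = [(t0, -3.5), (t0 + timedelta(days=305), -2.9)]
        ok, firing = gh_clinical_response(series, [(t0, None)])
        assert ok and firing.rule == "gh_clinical_response"

    def test_gain_of_04_is_not_a_response(self):
        t0 = date(2018, 1, 1)
        series = [(t0, -3.5), (t0 + timedelta(days=365), -3.1)]
        ok, _ = gh_clinical_response(series, [(t0, None)])
        assert not ok

    def test_off_treatment_points_do_not_count(self):
        t0 = date(2018, 1, 1)
        series = [(t0, -3.5), (t0 + timedelta(days=300), -2.5)]
        ok, _ = gh_clinical_response(series, [(t0 + timedelta(days=400), None)])
        assert not ok

    def test_matches_brute_force_all_pairs_scan(self):
        rng = random.Random(13)
        t0 = date(2016, 1, 1)
        for _ in range(50):
            n = rng.randint(2, 8)
            series = sorted(
                (t0 + timedelta(days=rng.randint(0, 1500)),
                 rng.uniform(-4.0, -1.0)) for _ in range(n))
            exp_start = t0 + timedelta(days=rng.randint(0, 700))
            exposures = [(exp_start, exp_start + timedelta(days=rng.randint(100, 900)))]
            got, _ = gh_clinical_response(series, exposures)
            on = [(d, z) for d, z in series
                  if exposures[0][0] <= d <= exposures[0][1]]
            expected = any(
                (d2 - d1).days <= 366 and z2 - z1 > 0.5
                for i, (d1, z1) in enumerate(on) for d2, z2 in on[i + 1:])
            assert got == expected


class TestIGF1Normalization:
    def test_spontaneous_normalization_off_gh(self):
        idx = cls("r0", date(2015, 1, 1), True)
        series = [idx, cls("r1", date(2015, 11, 25), False)]  # ~10.8 months
        kind, event = igf1_normalization(series, idx, exposures=[])
        assert kind == "spontaneous"
        months = (event.collection_date - idx.collection_date).days / 30.4375
        assert months == pytest.approx(10.8, abs=0.2)

    def test_normalization_on_treatment(self):
        idx = cls("r0", date(2015, 1, 1), True)
        series = [idx, cls("r1", date(2015, 7, 1), False)]
        kind, _ = igf1_normalization(series, idx,
                                     exposures=[(date(2015, 2, 1), None)])
        assert kind == "on_treatment"

    def test_all_low_never_normalizes(self):
        idx = cls("r0", date(2015, 1, 1), True)
        series = [idx, cls("r1", date(2016, 1, 1), True),
                  cls("r2", date(2017, 1, 1), True)]
        assert igf1_normalization(series, idx, exposures=[]) == ("none", None)


class TestGrowthNormalization:
    def test_recovery_above_minus2(self):
        t0 = date(2015, 1, 1)
        series = [(t0, -3.2), (t0 + timedelta(days=900), -1.8)]
        ok, firing = growth_normalization(series, [])
        assert ok and firing.rule == "growth_normalization"

    def test_flat_trajectory_is_not_normalization(self):
        t0 = date(2015, 1, 1)
        series = [(t0 + timedelta(days=200 * k), -3.3) for k in range(5)]
        ok, _ = growth_normalization(series, [])
        assert not ok

    def test_matches_brute_force_rule_evaluation(self):
        rng = random.Random(29)
        t0 = date(2015, 1, 1)
        for _ in range(50):
            series = sorted(
                (t0 + timedelta(days=rng.randint(0, 1800)),
                 rng.uniform(-4.0, -1.0)) for _ in range(rng.randint(2, 8)))
            got, _ = growth_normalization(series, [])
            zs = [z for _, z in series]
            expected = (any(z <= -3.0 for z in zs) and zs[-1] > -2.0) or any(
                (d2 - d1).days <= 366 and z2 - z1 > 0.5
                for i, (d1, z1) in enumerate(series)
                for d2, z2 in series[i + 1:])
            assert got == expected


class TestVerdicts:
    def test_precedence_gh_over_spontaneous(self):
        v = verdict_from_flags(gh_treated=True, good_clinical_response=True,
                               spont_igf1_norm=True, spont_growth_norm=True)
        assert v == Verdict.EXCLUDED_GH_RESPONSE

    def test_lab_only_response_is_gh_related(self):
        # IGF-1 normalization on GH therapy excludes even with a poor
        # clinical response
        v = verdict_from_flags(gh_treated=True, igf1_normalized_on_gh=True)
        assert v == Verdict.EXCLUDED_GH_RESPONSE

    def test_spontaneous_combinations(self):
        assert verdict_from_flags(spont_igf1_norm=True, spont_growth_norm=True) \
            == Verdict.EXCLUDED_SPONT_BOTH
        assert verdict_from_flags(spont_igf1_norm=True) \
            == Verdict.EXCLUDED_SPONT_IGF1
        assert verdict_from_flags(spont_growth_norm=True) \
            == Verdict.EXCLUDED_SPONT_GROWTH
        assert verdict_from_flags() == Verdict.SPIGFD_CANDIDATE

    def test_gh_deficiency_trumps_everything(self):
        v = verdict_from_flags(gh_deficient=True, gh_treated=True,
                               good_clinical_response=True)
        assert v == Verdict.EXCLUDED_GH_DEFICIENT

    def test_true_spigfd_archetype_survives(self):
        # persistently low IGF-1, no GH therapy, heights pinned below -3:
        # no exclusion rule may fire
        from spigfd.longitudinal_review import review_candidate
        t0 = date(2015, 1, 1)
        series = [cls(f"r{k}", t0 + timedelta(days=180 * k), True)
                  for k in range(8)]
        heights = [(t0 + timedelta(days=180 * k), -3.4 + 0.01 * k)
                   for k in range(8)]
        outcome, months = review_candidate(
            patient_id="P1", index=series[0], classifications=series,
            height_z_series=heights, stim_tests=[(date(2016, 1, 1), 9.0)],
            exposures=[])
        assert outcome.verdict == Verdict.SPIGFD_CANDIDATE
        assert months is None

    def test_verdict_stable_under_permuted_inputs(self):
        from spigfd.longitudinal_review import review_candidate
        t0 = date(2015, 1, 1)
        series = [cls("r0", t0, True), cls("r1", t0 + timedelta(days=330), False)]
        heights = [(t0, -3.2), (t0 + timedelta(days=900), -1.7)]
        rng = random.Random(1)
        verdicts = set()
        for _ in range(5):
            s, h = list(series), list(heights)
            rng.shuffle(s)
            rng.shuffle(h)
            outcome, _ = review_candidate(
                patient_id="P1", index=series[0], classifications=s,
                height_z_series=h, stim_tests=[], exposures=[])
            verdicts.add(outcome.verdict)
        assert verdicts == {Verdict.EXCLUDED_SPONT_BOTH}


class TestCaseSummaryReview:
    @pytest.mark.parametrize("text,lab,clin", [
        ("Good laboratory and clinical response", True, True),
        ("Good laboratory response; poor clinical response", True, False),
        ("N/A", False, False),
    ])
    def test_descriptor_parsing(self, text, lab, clin):
        assert parse_response_descriptor(text) == (lab, clin)

    def test_fixture_rows_classify_as_reviewed(self):
        table = case_table_fixture().set_index("study_id")
        outcomes = {o.patient_id: o.verdict
                    for o in review_case_summaries(table.reset_index())}
        assert outcomes["IGF22"] == Verdict.EXCLUDED_GH_RESPONSE
        assert outcomes["IGF08"] == Verdict.EXCLUDED_GH_RESPONSE
        assert outcomes["IGF37"] == Verdict.EXCLUDED_SPONT_BOTH
        assert outcomes["IGF50"] == Verdict.EXCLUDED_SPONT_IGF1

    def test_fixture_verdict_breakdown(self):
        outcomes = review_case_summaries(case_table_fixture())
        counts = verdict_counts(outcomes)
        assert counts["excluded_gh_response"] == 5
        assert counts["excluded_spont_igf1"] == 4
        assert counts["excluded_spont_both"] == 2
        assert counts["spigfd_candidate"] == 0
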