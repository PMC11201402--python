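"""Steps 5-6: GH-deficiency screen, trajectory review and final verdicts.

A candidate surviving the case-finding funnel is excluded when any of the
following holds, in precedence order:

1. GH deficiency — maximum stimulated peak GH below the analyzer-specific
   cutoff (5.4 ng/mL on Dxl, 7.4 ng/mL on Roche, strict inequality).
2. GH-treatment-related — a good clinical response to GH therapy (absolute
   height gain > 0.5 SDS between two on-treatment measurements at most 12
   months apart) or normalization of IGF-1 while on GH therapy.
3. Spontaneous normalization of both growth and IGF-1.
4. Spontaneous normalization of IGF-1 alone.
5. Spontaneous normalization of growth alone.

A patient clearing every rule keeps the ``spigfd_candidate`` verdict. Severe
primary IGF-1 deficiency cannot spontaneously normalize, so persistent low
IGF-1 with persistent short stature and no GH response is exactly the
phenotype that survives.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .growth_reference import DAYS_PER_MONTH, GrowthReferenceTable, MeasureKind, age_in_months
from .igf1_reference import (
    DEFAULT_GH_CALENDAR,
    GH_PEAK_THRESHOLDS,
    AssayCalendar,
    IGF1Classification,
)


class Verdict(str, enum.Enum):
    SPIGFD_CANDIDATE = "spigfd_candidate"
    EXCLUDED_GH_RESPONSE = "excluded_gh_response"
    EXCLUDED_SPONT_IGF1 = "excluded_spont_igf1"
    EXCLUDED_SPONT_GROWTH = "excluded_spont_growth"
    EXCLUDED_SPONT_BOTH = "excluded_spont_both"
    EXCLUDED_GH_DEFICIENT = "excluded_gh_deficient"
    EXCLUDED_OTHER_SECONDARY = "excluded_other_secondary"


#: Verdicts counted as GH-treatment-related exclusions in reports.
GH_RELATED_VERDICTS = frozenset({Verdict.EXCLUDED_GH_RESPONSE})


@dataclass(frozen=True)
class RuleFiring:
    rule: str
    on_date: date | None
    detail: str


@dataclass(frozen=True)
class ReviewOutcome:
    patient_id: str
    verdict: Verdict
    evidence: tuple[RuleFiring, ...]


@dataclass(frozen=True)
class GHStimResult:
    patient_id: str
    test_date: date
    peak_gh: float
    analyzer_id: str
    is_deficient: bool


@dataclass
class NormalizationSummary:
    """Months from first low IGF-1 to first subsequent not-low result off GH."""

    months: list[float] = field(default_factory=list)

    @property
    def median(self) -> float | None:
        return statistics.median(self.months) if self.months else None

    @property
    def range(self) -> tuple[float, float] | None:
        return (min(self.months), max(self.months)) if self.months else None


def classify_stim_test(patient_id: str, test_date: date, peak_gh: float,
                       calendar: AssayCalendar = DEFAULT_GH_CALENDAR,
                       thresholds: dict[str, float] = GH_PEAK_THRESHOLDS,
                       ) -> GHStimResult:
    analyzer = calendar.assay_for_date(test_date)
    cutoff = thresholds[analyzer]
    return GHStimResult(patient_id=patient_id, test_date=test_date,
                        peak_gh=float(peak_gh), analyzer_id=analyzer,
                        is_deficient=bool(peak_gh < cutoff))


def gh_deficiency(stim_tests: list[tuple[date, float]], *,
                  patient_id: str = "",
                  calendar: AssayCalendar = DEFAULT_GH_CALENDAR,
                  thresholds: dict[str, float] = GH_PEAK_THRESHOLDS,
                  ) -> tuple[str, GHStimResult | None]:
    """Per-patient GH status from all stimulation tests.

    The patient is deficient iff the maximum peak across tests is below the
    cutoff of the analyzer in use when that maximum was measured. No tests
    means indeterminate — the patient stays under review (about half the
    reviewed cohort in practice never had a stimulation test).

    Returns (status, best_test) with status in {deficient, sufficient,
    indeterminate}.
    """
    if not stim_tests:
        return "indeterminate", None
    results = [classify_stim_test(patient_id, d, v, calendar, thresholds)
               for d, v in stim_tests]
    best = max(results, key=lambda r: (r.peak_gh, r.test_date))
    return ("deficient" if best.is_deficient else "sufficient"), best


def gh_clinical_response(height_z_series: list[tuple[date, float]],
                         exposures: list[tuple[date, date | None]], *,
                         gain_sds: float = 0.5, window_days: int = 366,
                         ) -> tuple[bool, RuleFiring | None]:
    """Good clinical response: on-treatment height gain > gain_sds within 12 months.

    Both measurements of the pair must fall inside a GH exposure interval and
    be at most ``window_days`` apart (366 absorbs leap years). Fewer than two
    on-treatment points is insufficient data, reported as no response.
    """
    def on_treatment(d: date) -> bool:
        return any(s <= d and (e is None or d <= e) for s, e in exposures)

    points = sorted((d, z) for d, z in height_z_series if on_treatment(d))
    if len(points) < 2:
        return False, None
    for i, (d1, z1) in enumerate(points):
        for d2, z2 in points[i + 1:]:
            if (d2 - d1).days <= window_days and (z2 - z1) > gain_sds:
                return True, RuleFiring(
                    "gh_clinical_response", d2,
                    f"height z {z1:+.2f} -> {z2:+.2f} over {(d2 - d1).days} d on GH")
    return False, None


def igf1_normalization(classifications: list[IGF1Classification],
                       index: IGF1Classification,
                       exposures: list[tuple[date, date | None]],
                       ) -> tuple[str, IGF1Classification | None]:
    """First not-low IGF-1 after the index low result.

    Returns (kind, event) with kind in {none, on_treatment, spontaneous}: the
    event is labelled on_treatment when its date falls inside a GH exposure
    interval, spontaneous otherwise.
    """
    later = [c for c in classifications
             if (c.collection_date, c.result_id)
             > (index.collection_date, index.result_id)]
    later.sort(key=lambda c: (c.collection_date, c.result_id))
    for c in later:
        if not c.is_low and c.stratifier_used is not None:
            on_gh = any(s <= c.collection_date and (e is None or c.collection_date <= e)
                        for s, e in exposures)
            return ("on_treatment" if on_gh else "spontaneous"), c
    return "none", None


def growth_normalization(height_z_series: list[tuple[date, float]],
                         exposures: list[tuple[date, date | None]], *,
                         recovered_above: float = -2.0,
                         prior_below: float = -3.0,
                         gain_sds: float = 0.5, window_days: int = 366,
                         ) -> tuple[bool, RuleFiring | None]:
    """Spontaneous normalization of growth, evaluated off GH therapy.

    True when the latest height SDS exceeds ``recovered_above`` after having
    been at or below ``prior_below``, or when any off-treatment pair at most
    12 months apart shows a gain above ``gain_sds``. The thresholds are
    package defaults (configurable): normalization of growth is a clinical
    judgement with no universal numeric rule.
    """
    def on_treatment(d: date) -> bool:
        return any(s <= d and (e is None or d <= e) for s, e in exposures)

    off = sorted((d, z) for d, z in height_z_series if not on_treatment(d))
    if len(off) < 2:
        return False, None
    ever_low = any(z <= prior_below for _, z in off)
    last_date, last_z = off[-1]
    if ever_low and last_z > recovered_above:
        return True, RuleFiring(
            "growth_normalization", last_date,
            f"height z recovered to {last_z:+.2f} after <= {prior_below:+.1f}")
    for i, (d1, z1) in enumerate(off):
        for d2, z2 in off[i + 1:]:
            if (d2 - d1).days <= window_days and (z2 - z1) > gain_sds:
                return True, RuleFiring(
                    "growth_normalization", d2,
                    f"off-GH height z gain {z2 - z1:+.2f} over {(d2 - d1).days} d")
    return False, None


def verdict_from_flags(*, gh_deficient: bool = False, gh_treated: bool = False,
                       good_clinical_response: bool = False,
                       igf1_normalized_on_gh: bool = False,
                       spont_igf1_norm: bool = False,
                       spont_growth_norm: bool = False) -> Verdict:
    """Map review findings to a single verdict under the documented precedence."""
    if gh_deficient:
        return Verdict.EXCLUDED_GH_DEFICIENT
    if gh_treated and (good_clinical_response or igf1_normalized_on_gh):
        return Verdict.EXCLUDED_GH_RESPONSE
    if spont_igf1_norm and spont_growth_norm:
        return Verdict.EXCLUDED_SPONT_BOTH
    if spont_igf1_norm:
        return Verdict.EXCLUDED_SPONT_IGF1
    if spont_growth_norm:
        return Verdict.EXCLUDED_SPONT_GROWTH
    return Verdict.SPIGFD_CANDIDATE


def review_candidate(*, patient_id: str,
                     index: IGF1Classification,
                     classifications: list[IGF1Classification],
                     height_z_series: list[tuple[date, float]],
                     stim_tests: list[tuple[date, float]],
                     exposures: list[tuple[date, date | None]],
                     gh_calendar: AssayCalendar = DEFAULT_GH_CALENDAR,
                     gain_sds: float = 0.5, window_days: int = 366,
                     growth_recovered_above: float = -2.0,
                     growth_prior_below: float = -3.0,
                     ) -> tuple[ReviewOutcome, float | None]:
    """Step-6 review of one candidate from raw evidence.

    Returns the outcome and, when IGF-1 normalized spontaneously, the months
    from the index low to the normalization event.
    """
    evidence: list[RuleFiring] = []
    status, best = gh_deficiency(stim_tests, patient_id=patient_id,
                                 calendar=gh_calendar)
    if status == "deficient":
        evidence.append(RuleFiring(
            "gh_deficiency", best.test_date,
            f"max peak GH {best.peak_gh:.1f} ng/mL below {best.analyzer_id} cutoff"))
    elif status == "indeterminate":
        evidence.append(RuleFiring(
            "gh_deficiency_indeterminate", None,
            "no stimulation test on file; not excluded"))

    gh_treated = bool(exposures)
    clin, clin_fire = gh_clinical_response(
        height_z_series, exposures, gain_sds=gain_sds, window_days=window_days)
    if clin_fire:
        evidence.append(clin_fire)

    norm_kind, norm_event = igf1_normalization(classifications, index, exposures)
    months_to_norm = None
    if norm_event is not None:
        months = (norm_event.collection_date - index.collection_date).days \
            / DAYS_PER_MONTH
        evidence.append(RuleFiring(
            "igf1_normalization", norm_event.collection_date,
            f"{norm_kind} normalization {months:.1f} mo after index low"))
        if norm_kind == "spontaneous":
            months_to_norm = months

    growth, growth_fire = growth_normalization(
        height_z_series, exposures, recovered_above=growth_recovered_above,
        prior_below=growth_prior_below, gain_sds=gain_sds,
        window_days=window_days)
    if growth_fire:
        evidence.append(growth_fire)

    verdict = verdict_from_flags(
        gh_deficient=(status == "deficient"),
        gh_treated=gh_treated,
        good_clinical_response=clin,
        igf1_normalized_on_gh=(norm_kind == "on_treatment"),
        spont_igf1_norm=(norm_kind == "spontaneous"),
        spont_growth_norm=growth,
    )
    outcome = ReviewOutcome(patient_id=patient_id, verdict=verdict,
                            evidence=tuple(evidence))
    if verdict not in (Verdict.EXCLUDED_SPONT_IGF1, Verdict.EXCLUDED_SPONT_BOTH):
        months_to_norm = None
    return outcome, months_to_norm


def step6_review(candidates, cohort, growth_tables, igf1_by_patient, *,
                 gh_calendar: AssayCalendar = DEFAULT_GH_CALENDAR,
                 gain_sds: float = 0.5, window_days: int = 366,
                 growth_recovered_above: float = -2.0,
                 growth_prior_below: float = -3.0,
                 ) -> tuple[list[ReviewOutcome], NormalizationSummary]:
    """Review every candidate case against the full longitudinal record.

    ``candidates`` is the step-4 output (objects carrying patient_id and the
    index IGF-1 classification); ``igf1_by_patient`` maps patient_id to the
    patient's full classified IGF-1 series.
    """
    height_table: GrowthReferenceTable = growth_tables[MeasureKind.HEIGHT_FOR_AGE]
    outcomes: list[ReviewOutcome] = []
    summary = NormalizationSummary()
    for cand in sorted(candidates, key=lambda c: c.patient_id):
        pid = cand.patient_id
        patient = cohort.patients[cohort.patients["patient_id"] == pid].iloc[0]
        heights = cohort.for_patient("observations", pid)
        heights = heights[heights["kind"] == "height_cm"]
        z_series: list[tuple[date, float]] = []
        for _, row in heights.iterrows():
            try:
                res = height_table.zscore(
                    patient["sex"],
                    age_in_months(patient["birth_date"], row["date"]),
                    row["value"])
            except Exception:
                continue
            z_series.append((row["date"], res.z))
        labs = cohort.for_patient("labs", pid)
        stim = labs[(labs["analyte"] == "gh_peak")
                    & (labs["context"].str.startswith("stimulation"))]
        stim_tests = [(row["date"], float(row["value"]))
                      for _, row in stim.iterrows()]
        meds = cohort.for_patient("medications", pid)
        gh_meds = meds[meds["drug_class"] == "gh_therapy"]
        exposures = [(row["start_date"], row["end_date"])
                     for _, row in gh_meds.iterrows()]
        outcome, months = review_candidate(
            patient_id=pid, index=cand.index_igf1,
            classifications=igf1_by_patient.get(pid, []),
            height_z_series=z_series, stim_tests=stim_tests,
            exposures=exposures, gh_calendar=gh_calendar, gain_sds=gain_sds,
            window_days=window_days,
            growth_recovered_above=growth_recovered_above,
            growth_prior_below=growth_prior_below)
        outcomes.append(outcome)
        if months is not None:
            summary.months.append(months)
    return outcomes, summary


# ---------------------------------------------------------------------------
# Review from chart-abstracted flags (case-summary records)
# ---------------------------------------------------------------------------

def parse_response_descriptor(text: str) -> tuple[bool, bool]:
    """(good_laboratory_response, good_clinical_response) from a descriptor.

    A good laboratory response means IGF-1 normalized on GH therapy; a good
    clinical response means adequate height gain. 'N/A' (no GH treatment)
    yields (False, False).
    """
    t = (text or "").strip().lower()
    if not t or t in {"n/a", "na", "none"}:
        return False, False
    good_lab = "good laboratory" in t
    good_clin = ("clinical response" in t and "poor clinical" not in t
                 and ("good" in t))
    return good_lab, good_clin


def review_case_summaries(records: pd.DataFrame) -> list[ReviewOutcome]:
    """Apply the step-6 verdict rules to chart-abstracted case summaries.

    ``records`` carries one row per reviewed patient with columns study_id,
    gh_treatment (Y/N), gh_response (free-text descriptor),
    spont_growth_norm (Y/N) and spont_igf1_norm (Y/N) — the shape a manual
    chart review produces.
    """
    outcomes: list[ReviewOutcome] = []
    for _, row in records.iterrows():
        gh_treated = str(row["gh_treatment"]).strip().upper() == "Y"
        good_lab, good_clin = parse_response_descriptor(str(row["gh_response"]))
        spont_growth = str(row["spont_growth_norm"]).strip().upper() == "Y"
        spont_igf1 = str(row["spont_igf1_norm"]).strip().upper() == "Y"
        verdict = verdict_from_flags(
            gh_treated=gh_treated,
            good_clinical_response=good_clin,
            igf1_normalized_on_gh=gh_treated and good_lab,
            spont_igf1_norm=spont_igf1,
            spont_growth_norm=spont_growth)
        evidence = []
        if gh_treated and good_clin:
            evidence.append(RuleFiring("gh_clinical_response", None,
                                       str(row["gh_response"])))
        if gh_treated and good_lab:
            evidence.append(RuleFiring("igf1_normalization", None,
                                       "IGF-1 normalized on GH therapy"))
        if spont_igf1:
            evidence.append(RuleFiring("igf1_normalization", None,
                                       "spontaneous IGF-1 normalization"))
        if spont_growth:
            evidence.append(RuleFiring("growth_normalization", None,
                                       "spontaneous growth normalization"))
        outcomes.append(ReviewOutcome(patient_id=str(row["study_id"]),
                                      verdict=verdict, evidence=tuple(evidence)))
    return outcomes


def verdict_counts(outcomes: list[ReviewOutcome]) -> dict[str, int]:
    counts = {v.value: 0 for v in Verdict}
    for o in outcomes:
        counts[o.verdict.value] += 1
    return counts
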