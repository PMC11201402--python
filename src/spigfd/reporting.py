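"""Pipeline orchestration and study-style reports.

``run_pipeline`` executes funnel steps 1-4 and the trajectory review on a
validated cohort and produces a JSON-serializable report: per-step counts and
retention percentages, descriptive statistics at the first low IGF-1,
abnormal-growth category counts with overlap accounting, and one case-summary
row per candidate. The report is a pure function of (cohort, references,
configuration); repeated runs are bitwise identical.

Percentage conventions follow epidemiological reporting practice: shares of
the short-stature denominator carry one decimal (half-up), shares within a
subset are whole percents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

from .case_finding import GROWTH_CATEGORIES, FunnelResult, run_case_finding
from .config import RunConfig
from .ehr_model import Cohort
from .growth_reference import MeasureKind, age_in_months
from .longitudinal_review import (
    NormalizationSummary,
    ReviewOutcome,
    Verdict,
    step6_review,
    verdict_counts,
)
from .synthetic_emr import ReferenceBundle

STEP_CRITERIA = {
    "step1_short_stature": "height-for-age at or below -3.0 SDS",
    "step2_low_igf1": "at least one IGF-1 below the assay 2.5th percentile",
    "step3_temporal_link": "short stature within one year of the low IGF-1",
    "step4_potential_spigfd": "no coded secondary cause, BMI at or above the "
                              "5th percentile",
    "step6_reviewed": "entering growth/IGF-1 trajectory review",
}


def percent_of(count: int, denom: int, decimals: int = 1) -> str:
    """Half-up percentage string, e.g. percent_of(233, 4863) == '4.8%'."""
    if denom == 0:
        share = Decimal(0)
    else:
        share = Decimal(count) * 100 / Decimal(denom)
    quantum = Decimal(1).scaleb(-decimals) if decimals else Decimal(1)
    rendered = share.quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{rendered}%"


def funnel_percentages(counts: Mapping[str, int]) -> dict[str, str]:
    """Retention percentages in both published formats.

    Steps are rendered against the short-stature denominator with one
    decimal; the potential-case share of the temporally linked subset is a
    whole percent.
    """
    order = [k for k in STEP_CRITERIA if k in counts]
    denom = counts[order[0]] if order else 0
    out = {k: percent_of(counts[k], denom, 1) for k in order}
    if {"step3_temporal_link", "step4_potential_spigfd"} <= set(counts):
        out["step4_of_step3"] = percent_of(
            counts["step4_potential_spigfd"], counts["step3_temporal_link"], 0)
    return out


def render_flowchart(counts: Mapping[str, int]) -> str:
    """Textual funnel: one block per step with criterion, count and share."""
    order = [k for k in STEP_CRITERIA if k in counts]
    denom = counts[order[0]] if order else 0
    blocks = []
    for key in order:
        blocks.append(f"[{key}] {STEP_CRITERIA[key]}\n"
                      f"    retained: {counts[key]} "
                      f"({percent_of(counts[key], denom, 1)})")
    return "\n".join(blocks)


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return float(np.mean(arr)), sd


@dataclass
class PipelineResult:
    funnel: FunnelResult
    outcomes: list[ReviewOutcome]
    normalization: NormalizationSummary
    report: dict = field(default_factory=dict)


def run_pipeline(cohort: Cohort, references: ReferenceBundle,
                 config: RunConfig | None = None) -> PipelineResult:
    """Execute funnel steps 1-4 and the step-6 review, and build the report."""
    config = config or RunConfig()
    th = config.thresholds
    funnel, series = run_case_finding(
        cohort, references.growth_tables, references.igf1_refs,
        config.igf1_calendar.build(),
        {k: tuple(v) for k, v in config.code_sets.items()},
        {k: tuple(v) for k, v in config.category_code_sets.items()},
        threshold_z=th.short_stature_z, inclusive=th.short_stature_inclusive,
        link_window_days=th.link_window_days,
        bmi_percentile=th.bmi_percentile,
        staging_window_days=th.staging_window_days)
    outcomes, normalization = step6_review(
        funnel.candidates, cohort, references.growth_tables, series,
        gh_calendar=config.gh_calendar.build(), gain_sds=th.gh_gain_sds,
        window_days=th.gh_window_days,
        growth_recovered_above=th.growth_recovered_above,
        growth_prior_below=th.growth_prior_below)
    report = build_report(cohort, references, funnel, outcomes, normalization)
    return PipelineResult(funnel=funnel, outcomes=outcomes,
                          normalization=normalization, report=report)


def build_report(cohort: Cohort, references: ReferenceBundle,
                 funnel: FunnelResult, outcomes: list[ReviewOutcome],
                 normalization: NormalizationSummary) -> dict:
    counts = {
        "step1_short_stature": len(funnel.step_sets.get("step1", ())),
        "step2_low_igf1": len(funnel.step_sets.get("step2", ())),
        "step3_temporal_link": len(funnel.step_sets.get("step3", ())),
        "step4_potential_spigfd": len(funnel.step_sets.get("step4", ())),
        "step6_reviewed": len(outcomes),
    }

    info = cohort.patients.set_index("patient_id")
    weight_t = references.growth_tables[MeasureKind.WEIGHT_FOR_AGE]
    height_t = references.growth_tables[MeasureKind.HEIGHT_FOR_AGE]
    ages, hz, wz, follow_up, delta_h = [], [], [], [], []
    n_female = 0
    category_counts = {c: 0 for c in GROWTH_CATEGORIES}
    multi_label = 0
    candidate_rows = []
    verdict_by_pid = {o.patient_id: o for o in outcomes}
    for cand in sorted(funnel.candidates, key=lambda c: c.patient_id):
        patient = info.loc[cand.patient_id]
        idx_date = cand.index_igf1.collection_date
        age_idx = age_in_months(patient["birth_date"], idx_date)
        ages.append(age_idx / 12.0)
        hz.append(cand.height_z_at_link)
        if patient["sex"] == "female":
            n_female += 1
        obs = cohort.for_patient("observations", cand.patient_id)
        weights = obs[obs["kind"] == "weight_kg"]
        if not weights.empty:
            gaps = (weights["date"] - idx_date).map(lambda d: abs(d.days))
            near = weights.loc[gaps[gaps == gaps.min()].index[0]]
            try:
                wz.append(weight_t.zscore(
                    patient["sex"],
                    age_in_months(patient["birth_date"], near["date"]),
                    near["value"]).z)
            except Exception:
                pass
        heights = obs[obs["kind"] == "height_cm"].sort_values("date")
        if len(heights) >= 2:
            first, last = heights.iloc[0], heights.iloc[-1]
            follow_up.append((last["date"] - first["date"]).days / 365.25)
            try:
                z_first = height_t.zscore(
                    patient["sex"],
                    age_in_months(patient["birth_date"], first["date"]),
                    first["value"]).z
                z_last = height_t.zscore(
                    patient["sex"],
                    age_in_months(patient["birth_date"], last["date"]),
                    last["value"]).z
                delta_h.append(z_last - z_first)
            except Exception:
                pass
        for label in cand.categories:
            category_counts[label] += 1
        if len(cand.categories) > 1:
            multi_label += 1
        outcome = verdict_by_pid.get(cand.patient_id)
        meds = cohort.for_patient("medications", cand.patient_id)
        gh_treated = (meds["drug_class"] == "gh_therapy").any()
        candidate_rows.append({
            "patient_id": cand.patient_id,
            "index_igf1_date": idx_date.isoformat(),
            "index_igf1_value": cand.index_igf1.value,
            "index_igf1_threshold": cand.index_igf1.threshold_applied,
            "linked_height_date": cand.linked_height_date.isoformat(),
            "height_z_at_link": round(cand.height_z_at_link, 2),
            "categories": sorted(cand.categories),
            "gh_treatment": "Y" if gh_treated else "N",
            "verdict": outcome.verdict.value if outcome else "",
        })

    mean_age, sd_age = _mean_sd(ages)
    mean_hz, sd_hz = _mean_sd(hz)
    mean_wz, sd_wz = _mean_sd(wz)
    mean_fu, sd_fu = _mean_sd(follow_up)
    mean_dh, sd_dh = _mean_sd(delta_h)

    def _fmt(mean, sd):
        if mean is None:
            return None
        return {"mean": round(mean, 1), "sd": round(sd, 1)}

    rng = normalization.range
    report = {
        "funnel": {
            "counts": counts,
            "percentages": funnel_percentages(counts),
        },
        "review": {
            "verdict_counts": verdict_counts(outcomes),
            "n_spigfd_candidates": sum(
                1 for o in outcomes if o.verdict == Verdict.SPIGFD_CANDIDATE),
            "spigfd_percent_of_reviewed": percent_of(
                sum(1 for o in outcomes
                    if o.verdict == Verdict.SPIGFD_CANDIDATE),
                len(outcomes), 1),
            "spontaneous_igf1_normalization_months": {
                "n": len(normalization.months),
                "median": (round(normalization.median, 1)
                           if normalization.median is not None else None),
                "range": ([round(rng[0], 1), round(rng[1], 1)]
                          if rng is not None else None),
            },
        },
        "descriptives": {
            "n_candidates": len(funnel.candidates),
            "percent_female": percent_of(n_female, len(funnel.candidates), 0),
            "age_years_at_first_low_igf1": _fmt(mean_age, sd_age),
            "height_z_at_first_low_igf1": _fmt(mean_hz, sd_hz),
            "weight_z_at_first_low_igf1": _fmt(mean_wz, sd_wz),
            "follow_up_years": _fmt(mean_fu, sd_fu),
            "change_in_height_sds": _fmt(mean_dh, sd_dh),
        },
        "categories": {
            "counts": category_counts,
            "patients_with_multiple_labels": multi_label,
        },
        "candidates": candidate_rows,
        "exclusions": [
            {"patient_id": e.patient_id, "step": e.step, "rule": e.rule,
             "detail": e.detail} for e in funnel.exclusions],
    }
    return report
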