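"""Assay-aware classification of IGF-1 results against 2.5th-percentile bounds.

A serum IGF-1 value counts as *low* when it falls strictly below the 2.5th
percentile of the reference distribution for the assay in use on the
collection date, stratified by sex and by the most physiologically specific
stratifier documented near the draw: Tanner stage if available, else bone
age, else chronological age. Puberty shifts IGF-1 norms far more than
calendar age, which motivates that precedence; it is configurable.

Reference bounds are vendor- and lot-specific, so real tables are user
supplied; the package bundles only a synthetic toy table for tests.
"""

from __future__ import annotations

import bisect
import enum
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .growth_reference import Sex


class UncoveredDateError(ValueError):
    """A collection date precedes the first calendar interval."""


@dataclass(frozen=True)
class AssayCalendar:
    """Ordered (assay_id, effective_from) intervals; also used for GH analyzers.

    A boundary date belongs to the newer assay: the interval for entry i is
    [effective_from_i, effective_from_{i+1}).
    """

    entries: tuple[tuple[str, date], ...]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("calendar needs at least one entry")
        dates = [d for _, d in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("effective_from dates must be strictly increasing")

    def assay_for_date(self, collection_date: date) -> str:
        dates = [d for _, d in self.entries]
        if collection_date < dates[0]:
            raise UncoveredDateError(
                f"{collection_date.isoformat()} precedes calendar start "
                f"{dates[0].isoformat()}")
        idx = bisect.bisect_right(dates, collection_date) - 1
        return self.entries[idx][0]


#: IGF-1 assay history: IDS-iSYS through September 2017, Liaison from October 2017.
DEFAULT_IGF1_CALENDAR = AssayCalendar((
    ("IDS-iSYS", date(2013, 11, 1)),
    ("Liaison", date(2017, 10, 1)),
))

#: GH analyzer history: Dxl until 2019-11-27, Roche from that day on.
DEFAULT_GH_CALENDAR = AssayCalendar((
    ("Dxl", date(2005, 1, 1)),
    ("Roche", date(2019, 11, 27)),
))

#: Analyzer-specific peak-GH cutoffs (ng/mL) defining GH deficiency.
GH_PEAK_THRESHOLDS = {"Dxl": 5.4, "Roche": 7.4}


class Stratifier(str, enum.Enum):
    TANNER_STAGE = "tanner_stage"
    BONE_AGE = "bone_age"
    CHRONOLOGICAL_AGE = "chronological_age"


#: Default precedence, most specific first.
DEFAULT_PRECEDENCE = (Stratifier.TANNER_STAGE, Stratifier.BONE_AGE,
                      Stratifier.CHRONOLOGICAL_AGE)


class IGF1ReferenceTable:
    """2.5th-percentile lower bounds keyed by (assay, sex, stratifier, stratum).

    Age strata are [stratum_lo, stratum_hi) intervals in months; Tanner strata
    are degenerate intervals with stratum_lo == stratum_hi in {1..5}. Intervals
    per (assay, sex, stratifier) must be non-overlapping and ordered.
    """

    COLUMNS = ["assay", "sex", "stratifier", "stratum_lo", "stratum_hi", "p2_5"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, self.COLUMNS].copy()
        frame["sex"] = frame["sex"].map(lambda s: Sex(s).value)
        frame["stratifier"] = frame["stratifier"].map(lambda s: Stratifier(s).value)
        for col in ("stratum_lo", "stratum_hi", "p2_5"):
            frame[col] = frame[col].astype(float)
        if (frame["p2_5"] <= 0).any():
            raise ValueError("p2_5 bounds must be positive")
        frame = frame.sort_values(
            ["assay", "sex", "stratifier", "stratum_lo"], kind="mergesort")
        for (assay, sex, strat), sub in frame.groupby(["assay", "sex", "stratifier"]):
            lo = sub["stratum_lo"].to_numpy()
            hi = sub["stratum_hi"].to_numpy()
            if strat == Stratifier.TANNER_STAGE.value:
                if not ((lo == hi) & (lo >= 1) & (lo <= 5)).all():
                    raise ValueError(
                        f"Tanner strata must be degenerate 1-5 ({assay}/{sex})")
                if len(set(lo)) != len(lo):
                    raise ValueError(f"duplicate Tanner strata ({assay}/{sex})")
            else:
                if not (hi > lo).all() or not (lo[1:] >= hi[:-1]).all():
                    raise ValueError(
                        f"overlapping or unordered age strata ({assay}/{sex}/{strat})")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def threshold(self, assay: str, sex: Sex | str, stratifier: Stratifier,
                  stratum_value: float) -> float | None:
        """p2_5 bound for one stratum value, or None when no entry applies."""
        sub = self._frame[
            (self._frame["assay"] == assay)
            & (self._frame["sex"] == Sex(sex).value)
            & (self._frame["stratifier"] == Stratifier(stratifier).value)]
        if sub.empty:
            return None
        if stratifier == Stratifier.TANNER_STAGE:
            hit = sub[sub["stratum_lo"] == float(stratum_value)]
        else:
            hit = sub[(sub["stratum_lo"] <= stratum_value)
                      & (stratum_value < sub["stratum_hi"])]
        if hit.empty:
            return None
        return float(hit.iloc[0]["p2_5"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IGF1ReferenceTable":
        frame = pd.read_csv(path, sep="\t")
        # Tanner strata may be encoded T1-T5 in files.
        for col in ("stratum_lo", "stratum_hi"):
            frame[col] = frame[col].map(
                lambda v: float(str(v).lstrip("Tt")) if isinstance(v, str) else float(v))
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        out = self._frame.copy()
        tanner = out["stratifier"] == Stratifier.TANNER_STAGE.value
        for col in ("stratum_lo", "stratum_hi"):
            out[col] = out[col].astype(object)
            out.loc[tanner, col] = out.loc[tanner, col].map(
                lambda v: f"T{int(v)}")
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class IGF1Classification:
    """One IGF-1 result judged against the applicable 2.5th-percentile bound.

    is_low is True iff value < threshold_applied strictly; a result with no
    applicable reference entry carries stratifier_used=None, a NaN threshold
    and is_low=False (unclassifiable results never exclude a patient).
    """

    result_id: str
    patient_id: str
    collection_date: date
    assay_id: str
    value: float
    stratifier_used: Stratifier | None
    threshold_applied: float
    is_low: bool
    notes: tuple[str, ...] = field(default=())


def classify_igf1(*, result_id: str, patient_id: str, value: float,
                  collection_date: date, sex: Sex | str, age_months: float,
                  tanner_stage: int | None = None,
                  bone_age_months: float | None = None,
                  refs: IGF1ReferenceTable,
                  calendar: AssayCalendar = DEFAULT_IGF1_CALENDAR,
                  precedence: tuple[Stratifier, ...] = DEFAULT_PRECEDENCE,
                  ) -> IGF1Classification:
    """Classify a single IGF-1 result.

    The first stratifier in ``precedence`` whose patient datum is present and
    whose reference entry covers the stratum is used. When none applies the
    result is unclassifiable: logged in ``notes`` and treated as not-low.
    """
    assay = calendar.assay_for_date(collection_date)
    available: dict[Stratifier, float] = {
        Stratifier.CHRONOLOGICAL_AGE: age_months}
    if tanner_stage is not None:
        available[Stratifier.TANNER_STAGE] = float(tanner_stage)
    if bone_age_months is not None:
        available[Stratifier.BONE_AGE] = float(bone_age_months)
    notes: list[str] = []
    for strat in precedence:
        if strat not in available:
            continue
        bound = refs.threshold(assay, sex, strat, available[strat])
        if bound is None:
            notes.append(f"no {strat.value} reference entry for {assay}")
            continue
        return IGF1Classification(
            result_id=result_id, patient_id=patient_id,
            collection_date=collection_date, assay_id=assay, value=float(value),
            stratifier_used=strat, threshold_applied=bound,
            is_low=bool(value < bound), notes=tuple(notes))
    notes.append("unclassifiable: no applicable reference entry; treated as not-low")
    return IGF1Classification(
        result_id=result_id, patient_id=patient_id,
        collection_date=collection_date, assay_id=assay, value=float(value),
        stratifier_used=None, threshold_applied=math.nan,
        is_low=False, notes=tuple(notes))


def nearest_staging(staging: pd.DataFrame, kind: str, on_date: date,
                    window_days: int) -> float | None:
    """Most recent-in-absolute-time staging value of a kind within a window.

    Ties in distance are broken toward the earlier record.
    """
    sub = staging[staging["kind"] == kind]
    if sub.empty:
        return None
    sub = sub.sort_values("date", kind="mergesort")
    gaps = (sub["date"] - on_date).map(lambda d: abs(d.days))
    ok = sub[gaps <= window_days]
    if ok.empty:
        return None
    ok_gaps = gaps[ok.index]
    best = ok.loc[ok_gaps[ok_gaps == ok_gaps.min()].index[0]]
    return float(best["value"])


def classify_patient_igf1(labs: pd.DataFrame, staging: pd.DataFrame,
                          *, patient_id: str, sex: Sex | str, birth_date: date,
                          refs: IGF1ReferenceTable,
                          calendar: AssayCalendar = DEFAULT_IGF1_CALENDAR,
                          precedence: tuple[Stratifier, ...] = DEFAULT_PRECEDENCE,
                          staging_window_days: int = 365,
                          ) -> list[IGF1Classification]:
    """Classify all basal IGF-1 results of one patient, time-ordered.

    ``labs`` and ``staging`` are that patient's rows of the cohort tables.
    Each lab is paired with the nearest Tanner stage and bone-age read within
    ``staging_window_days`` of the draw.
    """
    from .growth_reference import age_in_months

    igf = labs[(labs["analyte"] == "igf1") & (labs["context"] == "basal")]
    igf = igf.sort_values(["date", "result_id"], kind="mergesort")
    out: list[IGF1Classification] = []
    for _, row in igf.iterrows():
        tanner = nearest_staging(staging, "tanner_stage", row["date"],
                                 staging_window_days)
        bone = nearest_staging(staging, "bone_age_months", row["date"],
                               staging_window_days)
        out.append(classify_igf1(
            result_id=str(row["result_id"]), patient_id=patient_id,
            value=float(row["value"]), collection_date=row["date"],
            sex=sex, age_months=age_in_months(birth_date, row["date"]),
            tanner_stage=None if tanner is None else int(tanner),
            bone_age_months=bone, refs=refs, calendar=calendar,
            precedence=precedence))
    return out


def first_low_igf1(classifications: list[IGF1Classification]
                   ) -> IGF1Classification | None:
    """Earliest low classification; same-date ties go to the smaller result_id."""
    lows = [c for c in classifications if c.is_low]
    if not lows:
        return None
    return min(lows, key=lambda c: (c.collection_date, c.result_id))
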