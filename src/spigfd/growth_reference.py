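"""Anthropometric z-scores from LMS growth-reference tables.

The LMS method summarises a growth reference as three age- and sex-specific
curves: Box-Cox power L(t), median M(t) and coefficient of variation S(t).
A measurement X at age t maps to a standard-deviation score (SDS)

    z = ((X/M)^L - 1) / (L*S)      for L != 0
    z = ln(X/M) / S                for L == 0

Real references (e.g. the WHO growth charts used in Canadian practice) are
supplied by the user as tab-separated LMS grids; the package bundles only a
small synthetic grid for tests (see :mod:`spigfd.synthetic_emr`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

#: |L| below this uses the logarithmic branch of the LMS transform.
LOG_BRANCH_TOL = 1e-7

#: Mean Gregorian month length in days; converts exact day ages to months.
DAYS_PER_MONTH = 30.4375


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class MeasureKind(str, enum.Enum):
    HEIGHT_FOR_AGE = "height_for_age"
    WEIGHT_FOR_AGE = "weight_for_age"
    BMI_FOR_AGE = "bmi_for_age"


class InvalidMeasurementError(ValueError):
    """Raised for non-positive measurement or LMS parameters."""


class AgeOutOfRangeError(LookupError):
    """Raised when a query age falls outside the reference grid.

    The message names the covered interval; the table never extrapolates.
    """


def age_in_months(birth_date: date, on_date: date) -> float:
    """Exact age in months: days since birth divided by 30.4375."""
    return (on_date - birth_date).days / DAYS_PER_MONTH


def zscore_lms(value: float, L: float, M: float, S: float,
               *, log_branch_tol: float = LOG_BRANCH_TOL) -> float:
    """LMS transform of a single measurement to an SDS.

    Parameters
    ----------
    value : measurement in the units of M (cm, kg, kg/m^2).
    L, M, S : Box-Cox power, median, coefficient of variation.
    log_branch_tol : |L| below which the L->0 limit (log branch) is used.
    """
    if not (value > 0 and M > 0 and S > 0):
        raise InvalidMeasurementError(
            f"value, M and S must be positive (value={value}, M={M}, S={S})")
    if abs(L) > log_branch_tol:
        return ((value / M) ** L - 1.0) / (L * S)
    return math.log(value / M) / S


def value_from_zscore(z: float, L: float, M: float, S: float,
                      *, log_branch_tol: float = LOG_BRANCH_TOL) -> float:
    """Inverse LMS transform: the measurement sitting at a given SDS."""
    if not (M > 0 and S > 0):
        raise InvalidMeasurementError(f"M and S must be positive (M={M}, S={S})")
    if abs(L) > log_branch_tol:
        base = 1.0 + L * S * z
        if base <= 0:
            raise InvalidMeasurementError(
                f"z={z} outside the Box-Cox domain for L={L}, S={S}")
        return M * base ** (1.0 / L)
    return M * math.exp(S * z)


@dataclass(frozen=True)
class ZScoreResult:
    """One standardised measurement.

    percentile is the standard-normal CDF of z times 100, in (0, 100).
    interpolated is True when the LMS row was linearly interpolated
    between grid ages rather than read off a grid point.
    """

    z: float
    percentile: float
    source_age_months: float
    interpolated: bool


class GrowthReferenceTable:
    """Sex x age grid of L/M/S parameters for one measure.

    Invariants enforced at construction: ages strictly increasing per sex
    (no duplicates), M > 0 and S > 0 everywhere. Lookups outside the grid
    raise :class:`AgeOutOfRangeError`; there is no extrapolation, silent or
    otherwise, because thresholding at -3 SDS is only meaningful inside the
    reference's support.
    """

    COLUMNS = ["sex", "age_months", "L", "M", "S"]

    def __init__(self, measure_kind: MeasureKind, rows: pd.DataFrame):
        self.measure_kind = MeasureKind(measure_kind)
        frame = rows.loc[:, self.COLUMNS].copy()
        frame["sex"] = frame["sex"].map(lambda s: Sex(s).value)
        for col in ("age_months", "L", "M", "S"):
            frame[col] = frame[col].astype(float)
        if (frame["age_months"] < 0).any():
            raise ValueError("age_months must be non-negative")
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise ValueError("M and S must be positive on every row")
        frame = frame.sort_values(["sex", "age_months"], kind="mergesort")
        for sex, sub in frame.groupby("sex"):
            ages = sub["age_months"].to_numpy()
            if len(ages) < 2:
                raise ValueError(f"need >= 2 grid rows for sex={sex}")
            if not (np.diff(ages) > 0).all():
                raise ValueError(f"duplicate or non-increasing ages for sex={sex}")
        self._rows = frame.reset_index(drop=True)
        self._by_sex = {
            sex: (sub["age_months"].to_numpy(), sub["L"].to_numpy(),
                  sub["M"].to_numpy(), sub["S"].to_numpy())
            for sex, sub in frame.groupby("sex")
        }

    @property
    def rows(self) -> pd.DataFrame:
        return self._rows.copy()

    def age_range(self, sex: Sex | str) -> tuple[float, float]:
        ages = self._by_sex[Sex(sex).value][0]
        return float(ages[0]), float(ages[-1])

    def lookup(self, sex: Sex | str, age_months: float
               ) -> tuple[float, float, float, bool]:
        """(L, M, S, interpolated) at an age; componentwise linear interpolation."""
        key = Sex(sex).value
        if key not in self._by_sex:
            raise KeyError(f"no reference rows for sex={key}")
        ages, L, M, S = self._by_sex[key]
        if age_months < ages[0] or age_months > ages[-1]:
            raise AgeOutOfRangeError(
                f"age {age_months:.2f} mo outside {self.measure_kind.value} "
                f"reference for {key} (covered: {ages[0]:.2f}-{ages[-1]:.2f} mo)")
        idx = np.searchsorted(ages, age_months)
        if idx < len(ages) and ages[idx] == age_months:
            return float(L[idx]), float(M[idx]), float(S[idx]), False
        return (
            float(np.interp(age_months, ages, L)),
            float(np.interp(age_months, ages, M)),
            float(np.interp(age_months, ages, S)),
            True,
        )

    def zscore(self, sex: Sex | str, age_months: float, value: float) -> ZScoreResult:
        L, M, S, interpolated = self.lookup(sex, age_months)
        z = zscore_lms(value, L, M, S)
        return ZScoreResult(
            z=z,
            percentile=float(norm.cdf(z) * 100.0),
            source_age_months=float(age_months),
            interpolated=interpolated,
        )

    def value_at(self, sex: Sex | str, age_months: float, z: float) -> float:
        """Measurement sitting at SDS z; used by the synthetic generator."""
        L, M, S, _ = self.lookup(sex, age_months)
        return value_from_zscore(z, L, M, S)


def measure_zscore(table: GrowthReferenceTable, sex: Sex | str,
                   age_months: float, value: float) -> ZScoreResult:
    """Functional alias for :meth:`GrowthReferenceTable.zscore`."""
    return table.zscore(sex, age_months, value)


def bmi_from_observations(height_cm: float, weight_kg: float) -> float:
    """Body-mass index in kg/m^2 from a paired height and weight."""
    if not (height_cm > 0 and weight_kg > 0):
        raise InvalidMeasurementError("height and weight must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def paired_bmi(observations: pd.DataFrame, *, window_days: int = 0) -> pd.DataFrame:
    """Pair height and weight observations into BMI values.

    Heights and weights are paired per patient when their dates differ by at
    most ``window_days`` (default: same encounter date). An unpaired height or
    weight simply yields no BMI row at that date — a missing-pair signal, not
    an error. The BMI date is the height date; the nearest weight wins, earlier
    weight on ties.

    Returns a frame with columns patient_id, date, bmi.
    """
    heights = observations[observations["kind"] == "height_cm"]
    weights = observations[observations["kind"] == "weight_kg"]
    out: list[dict] = []
    weights_by_pid: dict[str, pd.DataFrame] = {
        pid: sub.sort_values("date") for pid, sub in weights.groupby("patient_id")}
    for _, h in heights.iterrows():
        sub = weights_by_pid.get(h["patient_id"])
        if sub is None:
            continue
        gaps = (sub["date"] - h["date"]).map(lambda d: abs(d.days))
        ok = sub[gaps <= window_days]
        if ok.empty:
            continue
        ok_gaps = gaps[ok.index]
        best = ok.loc[ok_gaps[ok_gaps == ok_gaps.min()].index[0]]
        out.append({
            "patient_id": h["patient_id"],
            "date": h["date"],
            "bmi": bmi_from_observations(h["value"], best["value"]),
        })
    return pd.DataFrame(out, columns=["patient_id", "date", "bmi"])


def load_reference_tables(path: str | Path) -> dict[MeasureKind, GrowthReferenceTable]:
    """Read a tab-separated reference file (columns: measure sex age_months L M S)."""
    frame = pd.read_csv(path, sep="\t")
    expected = ["measure", "sex", "age_months", "L", "M", "S"]
    if list(frame.columns) != expected:
        raise ValueError(f"reference file must have columns {expected}, "
                         f"got {list(frame.columns)}")
    tables: dict[MeasureKind, GrowthReferenceTable] = {}
    for measure, sub in frame.groupby("measure"):
        kind = MeasureKind(measure)
        tables[kind] = GrowthReferenceTable(kind, sub.drop(columns=["measure"]))
    return tables


def save_reference_tables(tables: dict[MeasureKind, GrowthReferenceTable],
                          path: str | Path) -> None:
    parts = []
    for kind in sorted(tables, key=lambda k: k.value):
        rows = tables[kind].rows
        rows.insert(0, "measure", kind.value)
        parts.append(rows)
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)
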