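"""Structured run configuration: thresholds, code sets, calendars, paths.

Every configurable decision of the pipeline lives here with its default, so a
run is a pure function of (cohort bundle, configuration). Configurations load
from and save to YAML.
"""

from __future__ import annotations

import re
from datetime import date
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .case_finding import DEFAULT_CATEGORY_CODE_SETS, DEFAULT_CODE_SETS
from .igf1_reference import (
    DEFAULT_GH_CALENDAR,
    DEFAULT_IGF1_CALENDAR,
    GH_PEAK_THRESHOLDS,
    AssayCalendar,
)

_PREFIX_PATTERN = re.compile(r"^[A-Z][0-9]{0,2}(\.[A-Za-z0-9]*)?$")


class Thresholds(BaseModel):
    """Numeric decision points, each mirroring a published criterion."""

    #: short-stature cutoff in SDS; inclusive comparison by default
    short_stature_z: float = Field(default=-3.0, ge=-5.0, le=-1.0)
    short_stature_inclusive: bool = True
    #: malnutrition proxy: BMI percentile lower bound for retention
    bmi_percentile: float = Field(default=5.0, gt=0.0, lt=50.0)
    #: symmetric window linking short stature to the index low IGF-1
    link_window_days: int = Field(default=365, ge=1)
    #: how recent a Tanner/bone-age read must be to stratify a lab
    staging_window_days: int = Field(default=365, ge=0)
    #: good GH clinical response: gain and window
    gh_gain_sds: float = Field(default=0.5, gt=0.0)
    gh_window_days: int = Field(default=366, ge=1)
    #: growth-normalization rule (package decision, no published formula)
    growth_recovered_above: float = -2.0
    growth_prior_below: float = -3.0


class CalendarEntry(BaseModel):
    assay_id: str
    effective_from: date


class CalendarSpec(BaseModel):
    entries: list[CalendarEntry]

    def build(self) -> AssayCalendar:
        return AssayCalendar(tuple((e.assay_id, e.effective_from)
                                   for e in self.entries))

    @classmethod
    def from_calendar(cls, calendar: AssayCalendar) -> "CalendarSpec":
        return cls(entries=[CalendarEntry(assay_id=a, effective_from=d)
                            for a, d in calendar.entries])


class RunConfig(BaseModel):
    """Complete pipeline configuration with published defaults."""

    cohort_dir: Path | None = None
    growth_reference_file: Path | None = None
    igf1_reference_file: Path | None = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    code_sets: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: dict(DEFAULT_CODE_SETS))
    category_code_sets: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_CODE_SETS))
    igf1_calendar: CalendarSpec = Field(
        default_factory=lambda: CalendarSpec.from_calendar(DEFAULT_IGF1_CALENDAR))
    gh_calendar: CalendarSpec = Field(
        default_factory=lambda: CalendarSpec.from_calendar(DEFAULT_GH_CALENDAR))
    gh_peak_thresholds: dict[str, float] = Field(
        default_factory=lambda: dict(GH_PEAK_THRESHOLDS))
    seed: int = 0

    @field_validator("code_sets", "category_code_sets")
    @classmethod
    def _check_prefixes(cls, value):
        for name, prefixes in value.items():
            for p in prefixes:
                if not _PREFIX_PATTERN.match(p):
                    raise ValueError(
                        f"code set {name!r}: {p!r} is not a valid ICD-10 prefix")
        return value

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = self.model_dump(mode="json")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
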