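"""Subgroup and sensitivity reruns of the signal-detection machinery.

Subgroups are defined by report-level predicates (sex, or an age interval in
years). The background for a stratum is re-restricted to the same stratum, so
each subgroup contrast compares target reports against comparable non-target
reports; comparing against the full database instead is available via
``restrict_background=False``.

The sensitivity rerun removes target reports that mention any of a list of
concomitant drugs (matched in any role after name normalization) from the
database and recomputes the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .coding import CodingTable, normalize_drugname
from .ingest import CaseReport
from .signals import Thresholds, signal_table


@dataclass(frozen=True)
class StratumSpec:
    """A named report-level filter: a sex value and/or an age interval.

    Age interval ends are inclusive by default, matching the common
    "18–65 / >65" table convention: 18–65 is 18 <= age <= 65 and >65 is built
    with ``min_inclusive=False``. Reports with missing age never match an age
    filter; reports with missing sex never match a sex filter.
    """

    name: str
    sex: str | None = None  # "male" / "female" / "missing"
    age_min: float | None = None
    age_max: float | None = None
    min_inclusive: bool = True
    max_inclusive: bool = True

    def matches(self, report: CaseReport) -> bool:
        if self.sex is not None and report.sex != self.sex:
            return False
        if self.age_min is not None or self.age_max is not None:
            age = report.age_years
            if age is None:
                return False
            if self.age_min is not None and (
                age < self.age_min or (age == self.age_min and not self.min_inclusive)
            ):
                return False
            if self.age_max is not None and (
                age > self.age_max or (age == self.age_max and not self.max_inclusive)
            ):
                return False
        return True


def sex_stratum(sex: Literal["male", "female", "missing"]) -> StratumSpec:
    return StratumSpec(name=f"sex={sex}", sex=sex)


def age_stratum(
    name: str,
    age_min: float | None = None,
    age_max: float | None = None,
    min_inclusive: bool = True,
    max_inclusive: bool = True,
) -> StratumSpec:
    return StratumSpec(name, None, age_min, age_max, min_inclusive, max_inclusive)


#: The usual pediatric / adult / elderly partition of non-missing ages.
DEFAULT_AGE_STRATA = (
    age_stratum("age<18", age_max=18, max_inclusive=False),
    age_stratum("age18-65", age_min=18, age_max=65),
    age_stratum("age>65", age_min=65, min_inclusive=False),
)


@dataclass(frozen=True)
class SensitivitySpec:
    """Concomitant-drug exclusion list (normalized names, matched in any role)."""

    exclusion_drugs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.exclusion_drugs:
            raise ValueError("exclusion_drugs must be non-empty")

    @property
    def normalized(self) -> set[str]:
        return {normalize_drugname(d) for d in self.exclusion_drugs}


def run_subgroup(
    reports: list[CaseReport],
    background: list[CaseReport],
    spec: StratumSpec,
    k: int | None = 50,
    target: Sequence[str] = (),
    level: Literal["pt", "soc"] = "pt",
    coding: CodingTable | None = None,
    thresholds: Thresholds = Thresholds(),
    restrict_background: bool = True,
) -> pd.DataFrame:
    """Signal table within one stratum; raises if the target stratum is empty."""
    sub_reports = [r for r in reports if spec.matches(r)]
    if not sub_reports:
        raise ValueError(f"stratum {spec.name!r} contains no target reports")
    sub_background = [r for r in background if spec.matches(r)] if restrict_background else background
    return signal_table(
        sub_reports, target, sub_background, level=level, coding=coding, k=k,
        thresholds=thresholds,
    )


def run_sensitivity(
    reports: list[CaseReport],
    background: list[CaseReport],
    spec: SensitivitySpec,
    k: int | None = 50,
    target: Sequence[str] = (),
    level: Literal["pt", "soc"] = "pt",
    coding: CodingTable | None = None,
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Rerun signal detection after excluding target reports that mention any
    of the concomitant drugs; returns the table and before/after counts."""
    names = spec.normalized
    excluded_ids = {r.primaryid for r in reports if r.has_drug(names)}
    kept_reports = [r for r in reports if r.primaryid not in excluded_ids]
    counts = {
        "n_target_before": len(reports),
        "n_target_excluded": len(excluded_ids),
        "n_target_after": len(kept_reports),
    }
    if not kept_reports:
        raise ValueError("sensitivity exclusion removed every target report")
    kept_background = [r for r in background if r.primaryid not in excluded_ids]
    table = signal_table(
        kept_reports, target, kept_background, level=level, coding=coding, k=k,
        thresholds=thresholds,
    )
    return table, counts
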