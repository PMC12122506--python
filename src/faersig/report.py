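"""Descriptive characteristics of a deduplicated, drug-selected report set."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .ingest import CaseReport


def pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 1 decimal (display convention).

    Computed in decimal arithmetic so that values such as 4362/7733 -> 56.4
    do not depend on binary-float rounding artefacts.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    value = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class Descriptives:
    """Counts and display percentages mirroring a clinical-characteristics table."""

    n_reports: int
    sex_counts: dict[str, int]
    sex_pct: dict[str, float]
    age_median: float | None
    age_iqr: tuple[float, float] | None
    age_band_counts: dict[str, int]
    age_band_pct: dict[str, float]
    top_countries: list[tuple[str, int, float]]
    reporter_counts: dict[str, int]
    reporter_pct: dict[str, float]
    year_counts: dict[int, int] = field(default_factory=dict)
    year_pct: dict[int, float] = field(default_factory=dict)


def describe(reports: list[CaseReport], n_top_countries: int = 5) -> Descriptives:
    """Tabulate sex, age (median/IQR and <18 / 18–65 / >65 bands), country,
    reporter type and reporting year. Percentages are against the total
    report count and rounded half-up to one decimal; every category set
    includes an explicit "missing" bucket so counts sum to the total.
    """
    if not reports:
        raise ValueError("cannot describe an empty report set")
    n = len(reports)

    sex_counts = {"male": 0, "female": 0, "missing": 0}
    reporter_counts = {
        "healthcare professional": 0,
        "non-healthcare professional": 0,
        "missing": 0,
    }
    ages = []
    age_bands = {"<18": 0, "18-65": 0, ">65": 0, "missing": 0}
    country_counts: dict[str, int] = {}
    year_counts: dict[int, int] = {}
    for r in reports:
        sex_counts[r.sex] += 1
        reporter_counts[r.reporter] += 1
        if r.age_years is None:
            age_bands["missing"] += 1
        else:
            ages.append(r.age_years)
            if r.age_years < 18:
                age_bands["<18"] += 1
            elif r.age_years <= 65:
                age_bands["18-65"] += 1
            else:
                age_bands[">65"] += 1
        if r.country:
            country_counts[r.country] = country_counts.get(r.country, 0) + 1
        if r.report_year is not None:
            year_counts[r.report_year] = year_counts.get(r.report_year, 0) + 1

    if ages:
        q25, q50, q75 = np.quantile(np.asarray(ages), [0.25, 0.5, 0.75])
        age_median, age_iqr = float(q50), (float(q25), float(q75))
    else:
        age_median, age_iqr = None, None

    top = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n_top_countries]
    return Descriptives(
        n_reports=n,
        sex_counts=sex_counts,
        sex_pct={k: pct(v, n) for k, v in sex_counts.items()},
        age_median=age_median,
        age_iqr=age_iqr,
        age_band_counts=age_bands,
        age_band_pct={k: pct(v, n) for k, v in age_bands.items()},
        top_countries=[(c, v, pct(v, n)) for c, v in top],
        reporter_counts=reporter_counts,
        reporter_pct={k: pct(v, n) for k, v in reporter_counts.items()},
        year_counts=dict(sorted(year_counts.items())),
        year_pct={y: pct(v, n) for y, v in sorted(year_counts.items())},
    )
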