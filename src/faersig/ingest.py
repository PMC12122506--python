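"""Parsing, deduplication and assembly of FAERS-style quarterly tables.

The public FAERS quarterly data files are dollar-delimited ASCII with one
header line (DEMO, DRUG, REAC, THER, ...). This module reads the four tables
used for signal detection, removes duplicate case versions following the
FDA-recommended rule (keep the version with the largest FDA receipt date,
breaking ties by the largest PRIMARYID), and joins the tables into unified
:class:`CaseReport` records.

Dates in FAERS are frequently partial (YYYYMM or YYYY). Partial dates are
imputed to the 1st of the month / July 1 of the year, but the original
precision is retained so that downstream time-to-onset analysis can exclude
imputed intervals.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .coding import normalize_drugname

TABLES = ("demo", "drug", "reac", "ther")

_EXPECTED_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "reporter_country", "occp_cod"],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
}

#: FAERS occupation codes regarded as healthcare professionals.
_HCP_CODES = {"MD", "PH", "OT", "HP", "RN"}
_NON_HCP_CODES = {"CN", "LW"}

ROLE_CODES = ("PS", "SS", "C", "I")


# ---------------------------------------------------------------------------
# dates


def parse_faers_date(raw: str | None) -> tuple[_dt.date | None, str]:
    """Parse a FAERS date string; returns ``(date, precision)``.

    precision is one of ``"full"``, ``"month"``, ``"year"``, ``"none"``.
    YYYYMM is imputed to the 1st of the month and YYYY to July 1, so that an
    imputed date sits near the middle of the period it abbreviates.
    """
    if raw is None:
        return None, "none"
    s = str(raw).strip()
    if not s.isdigit():
        return None, "none"
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:])), "full"
        if len(s) == 6:
            return _dt.date(int(s[:4]), int(s[4:]), 1), "month"
        if len(s) == 4:
            return _dt.date(int(s), 7, 1), "year"
    except ValueError:
        return None, "none"
    return None, "none"


def _fda_dt_key(raw: str) -> int:
    """Sort key for FDA_DT; unparseable dates sort smallest (never retained preferentially)."""
    s = str(raw).strip()
    return int(s) if s.isdigit() and len(s) == 8 else -1


_NON_DIGIT = re.compile(r"\D")


def _primaryid_key(raw: str) -> int:
    """Numeric sort key for PRIMARYID after stripping non-digits; -1 if no digits."""
    digits = _NON_DIGIT.sub("", str(raw))
    return int(digits) if digits else -1


# ---------------------------------------------------------------------------
# reading


@dataclass
class QuarterTables:
    """Raw parsed row collections for one quarter plus malformed-line tallies."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    n_malformed: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _read_dollar_file(path: Path) -> tuple[pd.DataFrame, int]:
    """Parse one dollar-delimited file; malformed lines are counted, not dropped silently."""
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ValueError(f"{path}: empty file, expected a header line")
        columns = [c.strip().lower() for c in header_line.split("$")]
        rows: list[list[str]] = []
        n_malformed = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != len(columns):
                n_malformed += 1
                continue
            rows.append(fields)
    frame = pd.DataFrame(rows, columns=columns, dtype=str)
    return frame, n_malformed


def quarter_filename(table: str, quarter_label: str) -> str:
    """e.g. ``("demo", "24Q1") -> "DEMO24Q1.txt"``."""
    return f"{table.upper()}{quarter_label}.txt"


def read_quarter(directory: str | Path, quarter_label: str) -> QuarterTables:
    """Read the DEMO/DRUG/REAC/THER files of one quarter.

    Raises
    ------
    FileNotFoundError
        If any of the four files is missing (the message names the file).
    ValueError
        If a header does not contain the expected columns.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    for table in TABLES:
        path = directory / quarter_filename(table, quarter_label)
        if not path.exists():
            raise FileNotFoundError(f"missing FAERS table file: {path}")
        frame, n_bad = _read_dollar_file(path)
        missing = [c for c in _EXPECTED_COLUMNS[table] if c not in frame.columns]
        if missing:
            raise ValueError(
                f"{path}: header mismatch; expected columns {_EXPECTED_COLUMNS[table]}, "
                f"found {list(frame.columns)} (missing {missing})"
            )
        frames[table] = frame
        malformed[table] = n_bad
    return QuarterTables(frames["demo"], frames["drug"], frames["reac"], frames["ther"], malformed)


def concat_quarters(quarters: Iterable[QuarterTables]) -> QuarterTables:
    qs = list(quarters)
    malformed: dict[str, int] = {}
    for q in qs:
        for k, v in q.n_malformed.items():
            malformed[k] = malformed.get(k, 0) + v
    return QuarterTables(
        *(pd.concat([q.table(t) for q in qs], ignore_index=True) for t in TABLES),
        n_malformed=malformed,
    )


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per CASEID: the largest FDA_DT, then the largest PRIMARYID.

    PRIMARYID is compared numerically after stripping non-digit characters;
    rows whose PRIMARYID carries no digits at all fall back to lexicographic
    comparison among themselves. The result is independent of input order and
    idempotent.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_fda_key"] = work["fda_dt"].map(_fda_dt_key)
    work["_pid_key"] = work["primaryid"].map(_primaryid_key)
    work = work.sort_values(
        ["caseid", "_fda_key", "_pid_key", "primaryid"], kind="mergesort"
    )
    out = work.groupby("caseid", sort=False).tail(1)
    out = out.drop(columns=["_fda_key", "_pid_key"])
    return out.sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# case assembly


@dataclass
class DrugEntry:
    """One drug row of a report: verbatim name, FAERS role code, therapy start."""

    drugname: str
    role: str  # PS / SS / C / I
    start_dt: _dt.date | None = None
    start_dt_precision: str = "none"

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown FAERS role code: {self.role!r}")


@dataclass
class CaseReport:
    """One deduplicated safety report with its drugs and reactions attached."""

    primaryid: str
    caseid: str
    fda_dt: int | None
    event_dt: _dt.date | None = None
    event_dt_precision: str = "none"
    sex: str = "missing"  # male / female / missing
    age_years: float | None = None
    country: str | None = None
    reporter: str = "missing"  # healthcare professional / non-healthcare professional / missing
    report_year: int | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)

    def has_drug(self, names: set[str], roles: Sequence[str] | None = None) -> bool:
        """True if any drug entry (optionally restricted to ``roles``) matches a normalized name."""
        for entry in self.drugs:
            if roles is not None and entry.role not in roles:
                continue
            if normalize_drugname(entry.drugname) in names:
                return True
        return False


def _norm_sex(raw: str) -> str:
    s = raw.strip().upper()
    if s == "M":
        return "male"
    if s == "F":
        return "female"
    return "missing"


def _norm_reporter(raw: str) -> str:
    s = raw.strip().upper()
    if s in _HCP_CODES:
        return "healthcare professional"
    if s in _NON_HCP_CODES:
        return "non-healthcare professional"
    return "missing"


def _norm_age(age_raw: str, cod_raw: str) -> float | None:
    """Normalize AGE/AGE_COD to years; unknown unit codes yield missing."""
    s = age_raw.strip()
    try:
        value = float(s)
    except ValueError:
        return None
    cod = cod_raw.strip().upper()
    if cod in ("", "YR"):
        years = value
    elif cod == "MON":
        years = value / 12.0
    elif cod == "DY":
        years = value / 365.25
    elif cod == "WK":
        years = value * 7.0 / 365.25
    elif cod == "DEC":
        years = value * 10.0
    else:
        return None
    return years if years >= 0 else None


@dataclass
class AssembleStats:
    n_demo: int = 0
    n_assembled: int = 0
    n_dropped_no_reaction: int = 0
    n_orphan_drug: int = 0
    n_orphan_reac: int = 0
    n_orphan_ther: int = 0


def assemble(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    ther: pd.DataFrame,
) -> tuple[list[CaseReport], AssembleStats]:
    """Join the four tables on PRIMARYID into :class:`CaseReport` records.

    ``demo`` must already be deduplicated. Reports with zero reaction rows are
    dropped (and counted); drug/reaction/therapy rows without a retained demo
    parent are counted as orphans, not fatal. Duplicate PTs within one report
    are collapsed to a single occurrence.
    """
    stats = AssembleStats(n_demo=len(demo))
    keep_ids = set(demo["primaryid"])

    drug_rows: dict[str, list[tuple[str, str, str]]] = {}
    for row in drug.itertuples(index=False):
        pid = row.primaryid
        if pid not in keep_ids:
            stats.n_orphan_drug += 1
            continue
        drug_rows.setdefault(pid, []).append((row.drug_seq, row.role_cod, row.drugname))

    reac_rows: dict[str, list[str]] = {}
    for row in reac.itertuples(index=False):
        pid = row.primaryid
        if pid not in keep_ids:
            stats.n_orphan_reac += 1
            continue
        reac_rows.setdefault(pid, []).append(row.pt)

    ther_rows: dict[tuple[str, str], str] = {}
    for row in ther.itertuples(index=False):
        pid = row.primaryid
        if pid not in keep_ids:
            stats.n_orphan_ther += 1
            continue
        key = (pid, row.dsg_drug_seq)
        # earliest parseable start date wins when a drug has several therapy rows
        prev = ther_rows.get(key)
        if prev is None or _start_sort_key(row.start_dt) < _start_sort_key(prev):
            ther_rows[key] = row.start_dt

    reports: list[CaseReport] = []
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        pts = reac_rows.get(pid)
        if not pts:
            stats.n_dropped_no_reaction += 1
            continue
        event_dt, event_prec = parse_faers_date(row.event_dt)
        fda_key = _fda_dt_key(row.fda_dt)
        drugs: list[DrugEntry] = []
        for seq, role, name in drug_rows.get(pid, []):
            start_raw = ther_rows.get((pid, seq))
            start_dt, start_prec = parse_faers_date(start_raw)
            role = role.strip().upper()
            if role not in ROLE_CODES:
                role = "C"
            drugs.append(DrugEntry(name, role, start_dt, start_prec))
        reports.append(
            CaseReport(
                primaryid=pid,
                caseid=row.caseid,
                fda_dt=fda_key if fda_key >= 0 else None,
                event_dt=event_dt,
                event_dt_precision=event_prec,
                sex=_norm_sex(row.sex),
                age_years=_norm_age(row.age, row.age_cod),
                country=row.reporter_country.strip() or None,
                reporter=_norm_reporter(row.occp_cod),
                report_year=fda_key // 10000 if fda_key >= 0 else None,
                drugs=drugs,
                reactions=sorted(set(p.strip() for p in pts if p.strip())),
            )
        )
    # a report whose only reaction rows were blank strings has no reactions
    retained = [r for r in reports if r.reactions]
    stats.n_dropped_no_reaction += len(reports) - len(retained)
    stats.n_assembled = len(retained)
    return retained, stats


def _start_sort_key(raw: str) -> tuple[int, int]:
    d, prec = parse_faers_date(raw)
    if d is None:
        return (1, 10**8)
    return (0, d.toordinal())


def select_primary_suspect(
    reports: list[CaseReport], drug_names: Sequence[str]
) -> list[CaseReport]:
    """Retain reports with >= 1 primary-suspect drug matching any of ``drug_names``.

    Matching is case-insensitive exact match after whitespace normalization
    (see :func:`faersig.coding.normalize_drugname`); substring matching is
    deliberately not used to avoid false positives on combination products.
    """
    if not drug_names:
        raise ValueError("drug_names must be non-empty")
    names = {normalize_drugname(n) for n in drug_names}
    return [r for r in reports if r.has_drug(names, roles=("PS",))]
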