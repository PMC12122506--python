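"""Synthetic FAERS-style data with known ground truth.

The generator emits the four quarterly tables (DEMO, DRUG, REAC, THER) in the
public dollar-delimited dialect, with the structural features that make
spontaneous-reporting pipelines hard to test on real data alone:

* duplicate case versions (same CASEID, later FDA_DT, larger PRIMARYID,
  occasionally altered demographics) so the dedup rule is genuinely exercised;
* partial EVENT_DT/START_DT values truncated to YYYYMM or YYYY;
* per-field missingness and mixed age-unit codes (YR/MON/DY/DEC);
* one report, many reactions (truncated-geometric count of categorical draws);
* injected drug–event associations of configurable relative risk for a target
  drug, against an otherwise independent background;
* Weibull-distributed onset times for target-drug reports.

Background reports draw one primary-suspect drug uniformly from the drug
vocabulary and their reactions from a uniform event distribution, so drug and
event are independent except for the injected pairs. For an injected pair the
event probability under the target drug is set to ``rr`` times the background
probability and the remaining (non-signal) event probabilities are rescaled to
sum to one — this keeps the injected per-draw rate ratio exactly ``rr``.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import CodingTable

_DEMO_COLS = ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
              "sex", "reporter_country", "occp_cod"]
_DRUG_COLS = ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"]
_REAC_COLS = ["primaryid", "caseid", "pt"]
_THER_COLS = ["primaryid", "caseid", "dsg_drug_seq", "start_dt"]


def default_missing_rates() -> dict[str, float]:
    """Per-field missingness approximating what large FAERS drug extracts show:
    age is missing in roughly half of reports, sex and reporter type rarely,
    and usable onset/start dates survive in only a minority of reports."""
    return {
        "age": 0.56,
        "sex": 0.07,
        "country": 0.02,
        "occp_cod": 0.02,
        "event_dt": 0.55,
        "start_dt": 0.45,
    }


@dataclass(frozen=True)
class SignalSpec:
    """One injected association: PT name, relative-risk multiplier, and an
    optional sex restriction ("F"/"M") limiting the injection to reports whose
    recorded sex matches (used to test subgroup detection)."""

    pt: str
    rr: float
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.rr < 0:
            raise ValueError("relative risk multiplier must be >= 0")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic FAERS extract.

    The default Weibull onset parameters (scale 138.2 days, shape 0.73) mirror
    the early-failure profile typical of oncology-drug adverse events. The
    vocabulary sizes are chosen so that at the default 50k cases a null
    drug–event pair still has ~10 expected target-drug reports, enough for the
    Wald ROR interval to be usably calibrated.
    """

    n_cases: int = 50_000
    n_drugs: int = 25
    n_events: int = 300
    n_socs: int = 20
    target_drug: str = "vismodegib"
    signal_spec: list[SignalSpec | tuple[str, float]] = field(default_factory=list)
    duplicate_rate: float = 0.10
    missing_rate_by_field: dict[str, float] = field(default_factory=default_missing_rates)
    partial_date_rate: float = 0.10
    tto_shape: float = 0.73
    tto_scale: float = 138.2
    max_reactions: int = 5
    reaction_geom_p: float = 0.55
    concomitant_spec: dict[str, float] = field(
        default_factory=lambda: {"imiquimod": 0.01, "5-fluorouracil": 0.01, "mupirocin": 0.005}
    )
    extra_drug_rate: float = 0.15
    start_date: _dt.date = _dt.date(2012, 1, 1)
    end_date: _dt.date = _dt.date(2024, 3, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_drugs < 1 or self.n_events < 1 or self.n_socs < 1:
            raise ValueError("vocabulary sizes and case count must be positive")
        if self.n_socs > self.n_events:
            raise ValueError("n_socs must not exceed n_events")
        probs = {"duplicate_rate": self.duplicate_rate,
                 "partial_date_rate": self.partial_date_rate,
                 "extra_drug_rate": self.extra_drug_rate,
                 **{f"missing[{k}]": v for k, v in self.missing_rate_by_field.items()},
                 **{f"concomitant[{k}]": v for k, v in self.concomitant_spec.items()}}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ValueError("Weibull onset parameters must be positive")
        if not 0 < self.reaction_geom_p <= 1 or self.max_reactions < 1:
            raise ValueError("invalid reaction-count distribution parameters")
        self.signal_spec = [
            s if isinstance(s, SignalSpec) else SignalSpec(*s) for s in self.signal_spec
        ]

    @property
    def drug_vocabulary(self) -> list[str]:
        return [self.target_drug] + [f"drug_{i:03d}" for i in range(1, self.n_drugs)]

    @property
    def event_vocabulary(self) -> list[str]:
        return [f"pt_{i:03d}" for i in range(1, self.n_events + 1)]

    @property
    def soc_vocabulary(self) -> list[str]:
        return [f"soc_{i:02d}" for i in range(1, self.n_socs + 1)]


@dataclass
class SyntheticBundle:
    """Generated row collections plus the ground truth used to make them."""

    demo_rows: pd.DataFrame
    drug_rows: pd.DataFrame
    reac_rows: pd.DataFrame
    ther_rows: pd.DataFrame
    truth: dict[tuple[str, str], float]
    truth_tto: tuple[float, float]  # (scale alpha, shape beta)
    n_cases: int = 0
    n_target_cases: int = 0
    n_duplicate_versions: int = 0
    n_target_concomitant: int = 0


def toy_coding_table(config: GeneratorConfig) -> CodingTable:
    """Deterministic surjective PT -> SOC map standing in for a licensed dictionary."""
    events = config.event_vocabulary
    socs = config.soc_vocabulary
    return CodingTable(
        {pt: socs[i % len(socs)] for i, pt in enumerate(events)},
        version_label="toy-v1",
    )


def _truncated_geometric(rng: np.random.Generator, p: float, k: int, size: int) -> np.ndarray:
    """Sample from Geometric(p) truncated to {1..k} by inverse CDF."""
    if size == 0:
        return np.zeros(0, dtype=int)
    u = rng.random(size)
    fk = 1.0 - (1.0 - p) ** k
    m = np.ceil(np.log1p(-u * fk) / math.log(1.0 - p)).astype(int)
    return np.clip(m, 1, k)


def _event_probs(config: GeneratorConfig, sex: str | None) -> np.ndarray:
    """Per-draw event probabilities for target-drug cases with recorded sex ``sex``."""
    n = config.n_events
    q = 1.0 / n
    probs = np.full(n, q)
    vocab = config.event_vocabulary
    index = {pt: i for i, pt in enumerate(vocab)}
    signal_idx = []
    for spec in config.signal_spec:
        if spec.pt not in index:
            raise ValueError(f"signal PT {spec.pt!r} not in the event vocabulary")
        if spec.sex is not None and spec.sex != sex:
            continue
        probs[index[spec.pt]] = spec.rr * q
        signal_idx.append(index[spec.pt])
    signal_mass = probs[signal_idx].sum() if signal_idx else 0.0
    if signal_mass >= 1.0:
        raise ValueError("injected signal probabilities exceed 1; reduce multipliers or grow n_events")
    rest = np.ones(n, dtype=bool)
    rest[signal_idx] = False
    probs[rest] = (1.0 - signal_mass) / rest.sum()
    return probs


def _fmt_dates(ordinals: np.ndarray) -> np.ndarray:
    """Ordinal day numbers -> YYYYMMDD strings."""
    days = ordinals - _dt.date(1970, 1, 1).toordinal()
    as_dt = days.astype("timedelta64[D]") + np.datetime64("1970-01-01")
    return np.char.replace(np.datetime_as_string(as_dt, unit="D"), "-", "")


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate one synthetic extract; bit-reproducible for a given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    mr = {**default_missing_rates(), **config.missing_rate_by_field}
    drug_vocab = config.drug_vocabulary
    event_vocab = np.array(config.event_vocabulary)
    known = set(config.event_vocabulary)
    for spec in config.signal_spec:
        if spec.pt not in known:
            raise ValueError(f"signal PT {spec.pt!r} not in the event vocabulary")

    caseid = (1_000_000 + np.arange(n)).astype(str)
    primaryid = np.char.add(caseid, "1")  # version-1 id = CASEID * 10 + 1

    drug_idx = rng.integers(0, config.n_drugs, n)
    is_target = drug_idx == 0

    sex = np.where(rng.random(n) < 0.60, "F", "M")
    sex[rng.random(n) < mr["sex"]] = ""

    age_years = np.clip(rng.normal(72.0, 13.0, n), 18.0, 100.0)
    age_cod = rng.choice(["YR", "MON", "DY", "DEC"], size=n, p=[0.92, 0.04, 0.02, 0.02])
    age_val = np.where(
        age_cod == "MON", np.rint(age_years * 12),
        np.where(age_cod == "DY", np.rint(age_years * 365.25),
                 np.where(age_cod == "DEC", np.rint(age_years / 10), np.rint(age_years))),
    ).astype(int).astype(str)
    age_missing = rng.random(n) < mr["age"]
    age_val[age_missing] = ""
    age_cod_out = np.where(age_missing, "", age_cod)

    country = rng.choice(["US", "FR", "CA", "DE", "GB"], size=n,
                         p=[0.90, 0.035, 0.025, 0.025, 0.015])
    country[rng.random(n) < mr["country"]] = ""

    occp = rng.choice(["MD", "PH", "OT", "CN", "LW"], size=n,
                      p=[0.20, 0.15, 0.13, 0.40, 0.12])
    occp[rng.random(n) < mr["occp_cod"]] = ""

    # therapy start, event and receipt dates (ordinals)
    lo = config.start_date.toordinal()
    hi = config.end_date.toordinal()
    start_ord = rng.integers(lo, hi - 400, n) if n else np.zeros(0, dtype=int)
    tto_days = np.where(
        is_target,
        np.rint(config.tto_scale * rng.weibull(config.tto_shape, n)),
        rng.integers(0, 365, n) if n else 0,
    ).astype(int)
    event_ord = start_ord + tto_days
    fda_ord = event_ord + rng.integers(3, 90, n) if n else np.zeros(0, dtype=int)

    fda_dt = _fmt_dates(fda_ord) if n else np.array([], dtype=str)
    event_dt = _fmt_dates(event_ord) if n else np.array([], dtype=str)
    start_dt = _fmt_dates(start_ord) if n else np.array([], dtype=str)

    # partial-date truncation, then missingness
    def degrade(dates: np.ndarray) -> np.ndarray:
        out = dates.copy()
        u = rng.random(n)
        to_month = u < config.partial_date_rate / 2
        to_year = (u >= config.partial_date_rate / 2) & (u < config.partial_date_rate)
        if to_month.any():
            out[to_month] = out[to_month].astype("U6")  # YYYYMMDD -> YYYYMM
        if to_year.any():
            out[to_year] = out[to_year].astype("U4")  # -> YYYY
        return out

    event_dt = degrade(event_dt)
    start_dt = degrade(start_dt)
    event_dt[rng.random(n) < mr["event_dt"]] = ""
    start_missing = rng.random(n) < mr["start_dt"]
    start_dt[start_missing] = ""

    # reactions: number per report, then categorical draws per probability group
    m = _truncated_geometric(rng, config.reaction_geom_p, config.max_reactions, n)
    reac_case_idx = np.repeat(np.arange(n), m)
    pt_idx = np.empty(reac_case_idx.size, dtype=int)
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    if config.signal_spec and any(s.sex is not None for s in config.signal_spec):
        for sex_val in ("F", "M", ""):
            groups.append((is_target & (sex == sex_val), _event_probs(config, sex_val or None)))
    else:
        groups.append((is_target, _event_probs(config, None)))
    for mask, probs in groups:
        sel = mask[reac_case_idx]
        pt_idx[sel] = rng.choice(config.n_events, size=int(sel.sum()), p=probs)
    sel_bg = (~is_target)[reac_case_idx]
    pt_idx[sel_bg] = rng.integers(0, config.n_events, int(sel_bg.sum()))
    reac_pts = event_vocab[pt_idx]

    # drug rows: one primary-suspect row per case, plus planted concomitants
    # for target cases and occasional unrelated extra drugs
    ps_names = np.array([drug_vocab[i] for i in drug_idx], dtype=object)
    shout = rng.random(n) < 0.10  # exercise name normalization downstream
    ps_names[shout] = np.char.upper(ps_names[shout].astype(str))

    drug_pid: list[str] = list(primaryid)
    drug_case: list[str] = list(caseid)
    drug_seq: list[str] = ["1"] * n
    drug_role: list[str] = ["PS"] * n
    drug_name: list[str] = list(ps_names)

    conco_hit = np.zeros(n, dtype=bool)
    for cname, cprob in sorted(config.concomitant_spec.items()):
        mask = is_target & (rng.random(n) < cprob)
        conco_hit |= mask
        for i in np.flatnonzero(mask):
            drug_pid.append(primaryid[i]); drug_case.append(caseid[i])
            drug_seq.append("0")  # renumbered per case below
            drug_role.append("C"); drug_name.append(cname)

    extra_mask = rng.random(n) < config.extra_drug_rate
    extra_drug = rng.integers(0, config.n_drugs, n)
    extra_role = rng.choice(["SS", "C", "I"], size=n, p=[0.4, 0.5, 0.1])
    for i in np.flatnonzero(extra_mask):
        drug_pid.append(primaryid[i]); drug_case.append(caseid[i])
        drug_seq.append("9")
        drug_role.append(str(extra_role[i])); drug_name.append(drug_vocab[extra_drug[i]])

    # renumber concomitant rows 2, 3, ... within each case
    seq_counter: dict[str, int] = {}
    for k_row in range(n, len(drug_pid)):
        if drug_seq[k_row] != "0":
            continue
        pid = drug_pid[k_row]
        seq_counter[pid] = seq_counter.get(pid, 1) + 1
        drug_seq[k_row] = str(seq_counter[pid])

    # therapy rows for the primary-suspect drug when its start date survived
    ther_keep = ~start_missing
    ther_pid = primaryid[ther_keep]
    ther_case = caseid[ther_keep]
    ther_start = start_dt[ther_keep]

    demo = pd.DataFrame(
        {
            "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt,
            "event_dt": event_dt, "age": age_val, "age_cod": age_cod_out,
            "sex": sex, "reporter_country": country, "occp_cod": occp,
        },
        columns=_DEMO_COLS,
    )
    drug = pd.DataFrame(
        {"primaryid": drug_pid, "caseid": drug_case, "drug_seq": drug_seq,
         "role_cod": drug_role, "drugname": drug_name},
        columns=_DRUG_COLS,
    )
    reac = pd.DataFrame(
        {"primaryid": primaryid[reac_case_idx], "caseid": caseid[reac_case_idx],
         "pt": reac_pts},
        columns=_REAC_COLS,
    )
    ther = pd.DataFrame(
        {"primaryid": ther_pid, "caseid": ther_case,
         "dsg_drug_seq": np.full(ther_pid.size, "1"), "start_dt": ther_start},
        columns=_THER_COLS,
    )

    # duplicate case versions: later receipt date, larger PRIMARYID, and with
    # some probability a re-reported (altered) age
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_idx = np.flatnonzero(dup_mask)
    if dup_idx.size:
        dup_fda = _fmt_dates(fda_ord[dup_idx] + rng.integers(1, 60, dup_idx.size))
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["primaryid"] = np.char.add(caseid[dup_idx], "2")
        dup_demo["fda_dt"] = dup_fda
        alter = rng.random(dup_idx.size) < 0.3
        new_age = np.rint(np.clip(rng.normal(72.0, 13.0, dup_idx.size), 18, 100)).astype(int)
        dup_demo.loc[alter, "age"] = new_age[alter].astype(str)
        dup_demo.loc[alter, "age_cod"] = "YR"
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        dup_ids = set(primaryid[dup_idx])
        for frame_name in ("drug", "reac", "ther"):
            frame = {"drug": drug, "reac": reac, "ther": ther}[frame_name]
            sub = frame[frame["primaryid"].isin(dup_ids)].copy()
            sub["primaryid"] = sub["caseid"].astype(str) + "2"
            if frame_name == "drug":
                drug = pd.concat([drug, sub], ignore_index=True)
            elif frame_name == "reac":
                reac = pd.concat([reac, sub], ignore_index=True)
            else:
                ther = pd.concat([ther, sub], ignore_index=True)

    truth = {
        (config.target_drug, spec.pt): spec.rr for spec in config.signal_spec
    }
    return SyntheticBundle(
        demo_rows=demo.astype(str),
        drug_rows=drug.astype(str),
        reac_rows=reac.astype(str),
        ther_rows=ther.astype(str),
        truth=truth,
        truth_tto=(config.tto_scale, config.tto_shape),
        n_cases=n,
        n_target_cases=int(is_target.sum()),
        n_duplicate_versions=int(dup_mask.sum()) if n else 0,
        n_target_concomitant=int(conco_hit.sum()),
    )


def write_faers_ascii(
    bundle: SyntheticBundle, directory: str | Path, quarter_label: str
) -> list[Path]:
    """Write the four tables as DOLLAR-delimited ASCII files for one quarter."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for table, frame in (
        ("demo", bundle.demo_rows), ("drug", bundle.drug_rows),
        ("reac", bundle.reac_rows), ("ther", bundle.ther_rows),
    ):
        path = directory / f"{table.upper()}{quarter_label}.txt"
        try:
            frame.to_csv(path, sep="$", index=False, lineterminator="\n")
        except OSError as exc:
            raise OSError(f"failed to write FAERS table {path}: {exc}") from exc
        paths.append(path)
    return paths
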