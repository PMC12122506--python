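"""Drug–event disproportionality statistics on fourfold tables.

For a target drug and one adverse event, the database splits into the
fourfold table

    a = target-drug reports with the event      b = target-drug reports without it
    c = other-drug reports with the event       d = other-drug reports without it

Four standard signal-detection statistics are computed per event:

* **ROR** — reporting odds ratio ``(a·d)/(b·c)`` with a Wald 95% CI on the
  log scale.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Yates-corrected chi-square of the table.
* **MGPS / EBGM** — DuMouchel's empirical-Bayes gamma–Poisson shrinker: counts
  ``a`` are modelled as Poisson with mean ``λ·E`` where ``E=(a+b)(a+c)/N`` is
  the expected count under independence and ``λ`` has a two-component gamma
  mixture prior fitted across all drug–event pairs. EBGM is the geometric mean
  of the posterior of ``λ``; EBGM05 its 5th posterior percentile.
* **BCPNN / IC** — information component. The default parameterization is the
  shrunk observed-to-expected ratio ``IC = log2[(a+0.5)/(E+0.5)]`` with a
  gamma-posterior lower credibility bound IC025; the classic moment
  approximation is available with ``method="moment"``.

Counting is report-level: a report contributes at most once to ``a`` for a
given event regardless of how many times the term is recorded in it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .coding import CodingTable, map_pt_to_soc
from .ingest import CaseReport, select_primary_suspect

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# tables


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold drug–event table; all cells are non-negative report counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence, (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def _event_sets(
    reports: Iterable[CaseReport],
    level: Literal["pt", "soc"],
    coding: CodingTable | None,
) -> list[set[str]]:
    if level == "pt":
        return [set(r.reactions) for r in reports]
    if coding is None:
        raise ValueError("SOC-level tables require a coding table")
    out = []
    for r in reports:
        socs = {map_pt_to_soc(pt, coding) for pt in r.reactions}
        out.append(socs)
    return out


def build_tables(
    reports: list[CaseReport] | None,
    target: Sequence[str],
    level: Literal["pt", "soc"] = "pt",
    background: list[CaseReport] | None = None,
    coding: CodingTable | None = None,
) -> dict[str, ContingencyTable]:
    """Build one fourfold table per event at PT or SOC level.

    ``background`` is the full deduplicated database *including* the target
    reports; ``reports`` are the target-drug reports (a subset of it, matched
    by PRIMARYID). When ``reports`` is None they are derived from
    ``background`` by primary-suspect matching against ``target``. Every event
    seen anywhere in the background gets a table, even with ``a = 0`` —
    filtering on minimum counts happens later.
    """
    if background is None or not background:
        raise ValueError("background database must be non-empty")
    if reports is None:
        reports = select_primary_suspect(background, list(target))
    target_ids = {r.primaryid for r in reports}
    n_target = len(target_ids)
    n_total = len(background)

    target_mentions: dict[str, int] = {}
    other_mentions: dict[str, int] = {}
    all_events: set[str] = set()
    sets = _event_sets(background, level, coding)
    for rep, events in zip(background, sets):
        bucket = target_mentions if rep.primaryid in target_ids else other_mentions
        for ev in events:
            bucket[ev] = bucket.get(ev, 0) + 1
            all_events.add(ev)

    tables: dict[str, ContingencyTable] = {}
    for ev in sorted(all_events):
        a = target_mentions.get(ev, 0)
        c = other_mentions.get(ev, 0)
        tables[ev] = ContingencyTable(a, n_target - a, c, n_total - n_target - c)
    return tables


# ---------------------------------------------------------------------------
# frequentist statistics


def ror_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """ROR and Wald 95% CI; any zero cell yields ``(nan, nan, nan)``.

    No Haldane 0.5 continuity correction is applied by default — an undefined
    statistic is reported as such rather than silently corrected.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return math.nan, math.nan, math.nan
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se)


def prr_stats(t: ContingencyTable, yates: bool = True) -> tuple[float, float]:
    """PRR and the (Yates-corrected, by default) chi-square of the table."""
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0:
        raise ValueError("PRR requires non-zero drug, comparator and event margins")
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d)) if t.c > 0 else math.nan
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if denom == 0:
        return prr, math.nan
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - t.n / 2, 0.0)
    chi2 = t.n * diff**2 / denom
    return prr, chi2


# ---------------------------------------------------------------------------
# MGPS / EBGM


@dataclass(frozen=True)
class MGPSPrior:
    """Two-component gamma mixture prior on the reporting-rate ratio λ.

    Component j is Gamma(shape=alpha_j, rate=beta_j); ``w`` is the weight of
    component 1. The default values are DuMouchel's canonical starting point,
    not a fitted prior.
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    w: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")


class ConvergenceError(RuntimeError):
    """Raised when the MGPS hyperparameter optimizer fails; carries the trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # marginal of Poisson(λE) with λ ~ Gamma(alpha, rate=beta): negative binomial
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * (math.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def mixture_loglik(a: np.ndarray, e: np.ndarray, prior: MGPSPrior) -> float:
    """Marginal log-likelihood of observed counts under the mixture prior."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    l1 = _nb_logpmf(a, e, prior.alpha1, prior.beta1)
    l2 = _nb_logpmf(a, e, prior.alpha2, prior.beta2)
    if prior.w == 0.0:
        return float(np.sum(l2))
    if prior.w == 1.0:
        return float(np.sum(l1))
    stacked = np.stack([l1 + math.log(prior.w), l2 + math.log(1.0 - prior.w)])
    return float(np.sum(special.logsumexp(stacked, axis=0)))


def _tables_to_arrays(tables: Iterable[ContingencyTable]) -> tuple[np.ndarray, np.ndarray]:
    a = []
    e = []
    for t in tables:
        if t.expected > 0:
            a.append(t.a)
            e.append(t.expected)
    return np.asarray(a, dtype=float), np.asarray(e, dtype=float)


def fit_mgps_prior(
    tables: Iterable[ContingencyTable] | None = None,
    *,
    counts: np.ndarray | None = None,
    expected: np.ndarray | None = None,
    init: MGPSPrior = MGPSPrior(),
    tol: float = 1e-8,
) -> MGPSPrior:
    """Fit the five mixture hyperparameters by marginal maximum likelihood.

    The optimization runs L-BFGS-B on log-transformed gamma parameters and a
    logit-transformed weight, starting from the canonical DuMouchel point
    (0.2, 0.1, 2.0, 4.0, 1/3); it is deterministic for given inputs.

    Either a collection of tables or explicit ``counts``/``expected`` arrays
    may be supplied. Pairs with ``E = 0`` carry no information and are dropped.
    """
    if counts is None or expected is None:
        if tables is None:
            raise ValueError("provide tables or counts+expected arrays")
        counts, expected = _tables_to_arrays(tables)
    a = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.size < 2:
        raise ValueError("MGPS prior fitting requires at least 2 drug–event pairs")

    def unpack(theta: np.ndarray) -> MGPSPrior:
        return MGPSPrior(
            float(np.exp(theta[0])),
            float(np.exp(theta[1])),
            float(np.exp(theta[2])),
            float(np.exp(theta[3])),
            float(special.expit(theta[4])),
        )

    trace: list[float] = []

    def objective(theta: np.ndarray) -> float:
        nll = -mixture_loglik(a, e, unpack(theta))
        trace.append(nll)
        return nll

    theta0 = np.array(
        [math.log(init.alpha1), math.log(init.beta1), math.log(init.alpha2),
         math.log(init.beta2), special.logit(init.w)]
    )
    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=[(-12, 12)] * 4 + [(-12, 12)],
        options={"ftol": tol, "maxiter": 500},
    )
    if not res.success:
        raise ConvergenceError(f"MGPS hyperparameter fit did not converge: {res.message}", trace)
    return unpack(res.x)


def _posterior_mixture(
    a: float, e: float, prior: MGPSPrior
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior of λ given count a: weight of component 1 and (shape, rate) pairs."""
    l1 = float(_nb_logpmf(np.array([a]), np.array([e]), prior.alpha1, prior.beta1)[0])
    l2 = float(_nb_logpmf(np.array([a]), np.array([e]), prior.alpha2, prior.beta2)[0])
    if prior.w in (0.0, 1.0):
        q1 = prior.w
    else:
        log_q1 = math.log(prior.w) + l1
        log_q2 = math.log(1 - prior.w) + l2
        m = max(log_q1, log_q2)
        q1 = math.exp(log_q1 - m) / (math.exp(log_q1 - m) + math.exp(log_q2 - m))
    return q1, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e)


def ebgm_stats(t: ContingencyTable, prior: MGPSPrior) -> tuple[float, float]:
    """EBGM (posterior geometric mean of λ) and EBGM05 (5th posterior percentile).

    The posterior is the two-component gamma mixture with updated shapes/rates
    and count-dependent weights; the percentile is found by bracketed root
    finding on the mixture CDF.
    """
    e = t.expected
    if e <= 0:
        return math.nan, math.nan
    q1, (s1, r1), (s2, r2) = _posterior_mixture(t.a, e, prior)
    mean_log = q1 * (special.digamma(s1) - math.log(r1)) + (1 - q1) * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q1) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    p1 = stats.gamma.ppf(0.05, s1, scale=1 / r1)
    p2 = stats.gamma.ppf(0.05, s2, scale=1 / r2)
    lo, hi = min(p1, p2), max(p1, p2)
    if math.isclose(lo, hi, rel_tol=1e-9):
        return ebgm, lo
    # the mixture quantile lies between the component quantiles; pad the
    # bracket so cdf/ppf round-trip error cannot leave both ends on one side
    lo *= 0.99
    hi *= 1.01
    for _ in range(60):
        if cdf(lo) <= 0.05:
            break
        lo *= 0.5
    for _ in range(60):
        if cdf(hi) >= 0.05:
            break
        hi *= 2.0
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12)
    return ebgm, float(ebgm05)


# ---------------------------------------------------------------------------
# BCPNN / IC


def bcpnn_stats(
    t: ContingencyTable, method: Literal["gamma", "moment"] = "gamma"
) -> tuple[float, float]:
    """Information component IC (bits) and its lower 95% credibility bound IC025.

    ``method="gamma"`` (default): IC = log2[(a+0.5)/(E+0.5)], and IC025 is the
    log2 of the 2.5th percentile of the Gamma(a+0.5, rate=E+0.5) posterior of
    the shrunk reporting-rate ratio. Defined for a = 0.

    ``method="moment"``: the classic moment approximation with Beta/Dirichlet
    priors (all pseudo-counts 1 at the pair level, 2 at the margins) and
    IC025 = E(IC) − 1.96·sd(IC).
    """
    if method == "gamma":
        e = t.expected
        ic = math.log2((t.a + 0.5) / (e + 0.5))
        lam025 = stats.gamma.ppf(0.025, t.a + 0.5, scale=1 / (e + 0.5))
        return ic, math.log2(lam025)
    if method != "moment":
        raise ValueError(f"unknown BCPNN method: {method}")
    a, n = t.a, t.n
    row = t.a + t.b
    col = t.a + t.c
    g11, a1, b1 = 1.0, 1.0, 1.0
    aa, bb = 2.0, 2.0
    g = g11 * (n + aa) * (n + bb) / ((row + a1) * (col + b1))
    e_ic = math.log2((a + g11) * (n + aa) * (n + bb) / ((n + g) * (row + a1) * (col + b1)))
    v_ic = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - row + aa - a1) / ((row + a1) * (1 + n + aa))
        + (n - col + bb - b1) / ((col + b1) * (1 + n + bb))
    ) / math.log(2) ** 2
    return e_ic, e_ic - Z95 * math.sqrt(v_ic)


# ---------------------------------------------------------------------------
# thresholds and assembly


@dataclass(frozen=True)
class Thresholds:
    """Per-algorithm positivity rules; comparisons at the boundary are inclusive
    for >=-style rules and strict for >-style rules, as written."""

    min_a: int = 3
    ror_enabled: bool = True
    prr_enabled: bool = True
    mgps_enabled: bool = True
    bcpnn_enabled: bool = True
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ebgm05_min: float = 2.0
    mode: Literal["any", "all"] = "any"

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")


@dataclass
class SignalStats:
    """All four statistics for one drug–event pair (NaN marks undefined)."""

    event: str
    a: int
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan


def compute_stats(
    event: str,
    t: ContingencyTable,
    prior: MGPSPrior | None = None,
    bcpnn_method: Literal["gamma", "moment"] = "gamma",
) -> SignalStats:
    s = SignalStats(event=event, a=t.a)
    s.ror, s.ror_lo, s.ror_hi = ror_stats(t)
    try:
        s.prr, s.chi2 = prr_stats(t)
    except ValueError:
        pass
    if prior is not None:
        s.ebgm, s.ebgm05 = ebgm_stats(t, prior)
    s.ic, s.ic025 = bcpnn_stats(t, method=bcpnn_method)
    return s


def evaluate(s: SignalStats, th: Thresholds = Thresholds()) -> dict[str, bool]:
    """Apply the positivity rules; undefined (NaN) statistics evaluate negative.

    Returns per-algorithm flags plus ``combined`` (any-of by default, matching
    the convention that a pair is a signal when at least one rule fires).
    """
    flags = {
        "ror": bool(th.ror_enabled and s.a >= th.min_a and s.ror_lo > 1.0),
        "prr": bool(
            th.prr_enabled and s.a >= th.min_a and s.prr >= th.prr_min and s.chi2 >= th.chi2_min
        ),
        "mgps": bool(th.mgps_enabled and s.ebgm05 > th.ebgm05_min),
        "bcpnn": bool(th.bcpnn_enabled and s.ic025 > 0.0),
    }
    enabled = [
        flags[k]
        for k, on in (
            ("ror", th.ror_enabled),
            ("prr", th.prr_enabled),
            ("mgps", th.mgps_enabled),
            ("bcpnn", th.bcpnn_enabled),
        )
        if on
    ]
    flags["combined"] = any(enabled) if th.mode == "any" else bool(enabled) and all(enabled)
    return flags


def top_k_events(tables: dict[str, ContingencyTable], k: int) -> list[str]:
    """The k most frequent events by ``a``, ties broken alphabetically by term."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(tables.items(), key=lambda kv: (-kv[1].a, kv[0]))
    return [ev for ev, _ in ordered[:k]]


def signal_table(
    reports: list[CaseReport],
    target: Sequence[str],
    background: list[CaseReport],
    level: Literal["pt", "soc"] = "pt",
    coding: CodingTable | None = None,
    k: int | None = None,
    thresholds: Thresholds = Thresholds(),
    bcpnn_method: Literal["gamma", "moment"] = "gamma",
    prior: MGPSPrior | None = None,
) -> pd.DataFrame:
    """End-to-end signal table: tables → MGPS prior fit → all statistics → flags.

    The MGPS prior is fitted across *all* events at the chosen level (not just
    the top-k), then statistics are reported for the top-k most frequent events
    (all events when ``k`` is None). Returns a DataFrame mirroring the usual
    published layout, one row per event.
    """
    tables = build_tables(reports, target, level=level, background=background, coding=coding)
    if prior is None:
        counts, expected = _tables_to_arrays(tables.values())
        prior = fit_mgps_prior(counts=counts, expected=expected) if counts.size >= 2 else None
    events = top_k_events(tables, k) if k is not None else sorted(
        tables, key=lambda ev: (-tables[ev].a, ev)
    )
    rows = []
    for ev in events:
        t = tables[ev]
        s = compute_stats(ev, t, prior=prior, bcpnn_method=bcpnn_method)
        flags = evaluate(s, thresholds)
        rows.append(
            {
                "event": ev,
                "a": s.a,
                "ror": s.ror,
                "ror_lo": s.ror_lo,
                "ror_hi": s.ror_hi,
                "prr": s.prr,
                "chi2": s.chi2,
                "ebgm": s.ebgm,
                "ebgm05": s.ebgm05,
                "ic": s.ic,
                "ic025": s.ic025,
                "sig_ror": flags["ror"],
                "sig_prr": flags["prr"],
                "sig_mgps": flags["mgps"],
                "sig_bcpnn": flags["bcpnn"],
                "sig_combined": flags["combined"],
            }
        )
    return pd.DataFrame(rows)
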