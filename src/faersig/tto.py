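"""Time-to-onset (TTO) analysis and Weibull failure-mode classification.

TTO is the interval in days between the adverse-event onset date (EVENT_DT in
DEMO) and the start of therapy with the suspect drug (START_DT in THER). Only
intervals where both dates are recorded at full day precision and the event
follows therapy start are retained; everything else is tallied by exclusion
reason.

The retained onsets are modelled with a two-parameter Weibull distribution
with scale α (days) and shape β. The shape parameter classifies the hazard
over time: β < 1 means the event rate decreases with treatment duration
("early failure"), β ≈ 1 a constant rate ("random failure"), β > 1 an
increasing rate ("wear-out failure"). Classification uses the 95% CI of β,
not the point estimate, so "random failure" covers any CI that straddles 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .coding import normalize_drugname
from .ingest import CaseReport

Z95 = 1.959963984540054


@dataclass
class TTOSample:
    """Positive onset intervals in days plus tallies of excluded reports."""

    onsets: list[float] = field(default_factory=list)
    n_excluded_missing: int = 0
    n_excluded_negative: int = 0
    n_excluded_partial: int = 0

    @property
    def n(self) -> int:
        return len(self.onsets)


@dataclass
class WeibullFit:
    scale_alpha: float
    scale_ci: tuple[float, float]
    shape_beta: float
    shape_ci: tuple[float, float]
    failure_type: str  # "early failure" / "random failure" / "wear-out failure"
    loglik: float = math.nan


def compute_tto(
    reports: Sequence[CaseReport],
    drug_names: Sequence[str] | None = None,
    allow_imputed_dates: bool = False,
    include_same_day: bool = False,
) -> TTOSample:
    """Extract one onset interval per report.

    The start date is the earliest therapy start among the report's drug
    entries matching ``drug_names`` (all drugs when None). Same-day onsets
    (0 days) are excluded by default because the Weibull support is t > 0;
    ``include_same_day`` imputes them as half a day instead.

    Exclusion reasons, tallied per report:

    * missing — no event date or no usable therapy start date;
    * partial — either date only known to month or year precision
      (skipped when ``allow_imputed_dates``);
    * negative — event on/before therapy start.
    """
    names = {normalize_drugname(n) for n in drug_names} if drug_names else None
    sample = TTOSample()
    for rep in reports:
        starts = []
        partial_start = False
        for entry in rep.drugs:
            if names is not None and normalize_drugname(entry.drugname) not in names:
                continue
            if entry.start_dt is None:
                continue
            if entry.start_dt_precision != "full":
                partial_start = True
                if not allow_imputed_dates:
                    continue
            starts.append(entry.start_dt)
        if rep.event_dt is None or not starts:
            if rep.event_dt is not None and partial_start and not allow_imputed_dates:
                sample.n_excluded_partial += 1
            else:
                sample.n_excluded_missing += 1
            continue
        if rep.event_dt_precision != "full" and not allow_imputed_dates:
            sample.n_excluded_partial += 1
            continue
        delta = (rep.event_dt - min(starts)).days
        if delta < 0 or (delta == 0 and not include_same_day):
            sample.n_excluded_negative += 1
            continue
        sample.onsets.append(0.5 if delta == 0 else float(delta))
    return sample


def tto_summary(
    s: TTOSample, bin_edges: Sequence[float] = (0.0, 61.0, 181.0, math.inf)
) -> dict:
    """Median, IQR and proportions over half-open bins [lo, hi).

    Quantiles use linear interpolation (the type-7 definition), pinned so that
    medians and IQRs are reproducible. The default bins separate onsets in the
    first 60 days, days 61–180, and 181 days onward.
    """
    if not s.onsets:
        raise ValueError("empty onset sample")
    x = np.asarray(s.onsets, dtype=float)
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 linear interpolation
    edges = np.asarray(bin_edges, dtype=float)
    props = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        props.append(float(np.mean((x >= lo) & (x < hi))))
    return {
        "n": int(x.size),
        "median": float(q50),
        "iqr": (float(q25), float(q75)),
        "bin_edges": [float(e) for e in edges],
        "bin_proportions": props,
    }


def _weibull_loglik(x: np.ndarray, alpha: float, beta: float) -> float:
    z = x / alpha
    return float(
        x.size * (math.log(beta) - beta * math.log(alpha))
        + (beta - 1.0) * np.sum(np.log(x))
        - np.sum(z**beta)
    )


def _loglik_hessian(x: np.ndarray, la: float, lb: float, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the log-likelihood in (log α, log β)."""

    def f(p: np.ndarray) -> float:
        return _weibull_loglik(x, math.exp(p[0]), math.exp(p[1]))

    p0 = np.array([la, lb])
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pp = p0.copy(); pp[i] += h; pp[j] += h
            pm = p0.copy(); pm[i] += h; pm[j] -= h
            mp = p0.copy(); mp[i] -= h; mp[j] += h
            mm = p0.copy(); mm[i] -= h; mm[j] -= h
            hess[i, j] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * h * h)
    return hess


def fit_weibull(s: TTOSample | Sequence[float]) -> WeibullFit:
    """Maximum-likelihood two-parameter Weibull fit with Wald 95% CIs.

    CIs are computed on the log-parameter scale from the observed information
    (negative inverse Hessian of the log-likelihood at the MLE) and
    exponentiated, which keeps both bounds positive. Requires at least 10
    strictly positive onsets and a non-degenerate sample.
    """
    onsets = s.onsets if isinstance(s, TTOSample) else list(s)
    x = np.asarray(onsets, dtype=float)
    if x.size < 10:
        raise ValueError(f"Weibull fit requires >= 10 onsets, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("onsets must be strictly positive")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate sample: all onsets identical")

    shape, _, scale = stats.weibull_min.fit(x, floc=0)
    la, lb = math.log(scale), math.log(shape)
    hess = _loglik_hessian(x, la, lb)
    cov = np.linalg.inv(-hess)
    se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    scale_ci = (scale * math.exp(-Z95 * se_la), scale * math.exp(Z95 * se_la))
    shape_ci = (shape * math.exp(-Z95 * se_lb), shape * math.exp(Z95 * se_lb))

    if shape_ci[1] < 1.0:
        ftype = "early failure"
    elif shape_ci[0] > 1.0:
        ftype = "wear-out failure"
    else:
        ftype = "random failure"
    return WeibullFit(
        scale_alpha=float(scale),
        scale_ci=scale_ci,
        shape_beta=float(shape),
        shape_ci=shape_ci,
        failure_type=ftype,
        loglik=_weibull_loglik(x, scale, shape),
    )


def cumulative_incidence(s: TTOSample | Sequence[float], grid: Sequence[float]) -> np.ndarray:
    """Right-continuous empirical CDF of the onsets evaluated on ``grid``."""
    onsets = s.onsets if isinstance(s, TTOSample) else list(s)
    if not onsets:
        raise ValueError("empty onset sample")
    x = np.sort(np.asarray(onsets, dtype=float))
    g = np.asarray(grid, dtype=float)
    return np.searchsorted(x, g, side="right") / x.size
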