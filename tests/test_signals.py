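import math

import numpy as np
import pytest
from scipy import integrate, optimize, special, stats

from faersig.ingest import CaseReport, DrugEntry
from faersig.signals import (
    ContingencyTable,
    MGPSPrior,
    SignalStats,
    Thresholds,
    bcpnn_stats,
    build_tables,
    ebgm_stats,
    evaluate,
    fit_mgps_prior,
    mixture_loglik,
    prr_stats,
    ror_stats,
    top_k_events,
)

# ---------------------------------------------------------------------------
# independent oracles (closed forms / quadrature, coded separately from the
# implementation path)


def oracle_ror(a, b, c, d):
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return ror, math.exp(math.log(ror) - z * se), math.exp(math.log(ror) + z * se)


def oracle_prr_chi2(a, b, c, d):
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    diff = max(abs(a * d - b * c) - n / 2, 0.0)
    chi2 = n * diff * diff / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def oracle_ebgm(a, e, prior: MGPSPrior):
    """Quadrature over the unnormalized posterior density prior(λ)·Poisson(a; λE)."""

    def unnorm(lam):
        pr = prior.w * stats.gamma.pdf(lam, prior.alpha1, scale=1 / prior.beta1) + (
            1 - prior.w
        ) * stats.gamma.pdf(lam, prior.alpha2, scale=1 / prior.beta2)
        return pr * stats.poisson.pmf(a, lam * e)

    hi = max(50.0, 20.0 * (a + 1) / e)
    peak = [max(1e-6, a / e)]
    z, _ = integrate.quad(unnorm, 0, hi, limit=300, points=peak)
    mlog, _ = integrate.quad(lambda l: math.log(l) * unnorm(l) / z, 0, hi, limit=300, points=peak)

    def cdf(x):
        v, _ = integrate.quad(unnorm, 0, x, limit=300)
        return v / z

    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-9, hi)
    return math.exp(mlog), q05


def oracle_ic(a, e):
    """IC via the closed form; IC025 via gamma-quantile inversion on gammainc."""
    ic = math.log2((a + 0.5) / (e + 0.5))
    shape, rate = a + 0.5, e + 0.5

    def cdf(x):
        return special.gammainc(shape, rate * x)

    hi = (shape + 10 * math.sqrt(shape)) / rate
    lam025 = optimize.brentq(lambda x: cdf(x) - 0.025, 1e-12, hi)
    return ic, math.log2(lam025)


# ---------------------------------------------------------------------------
# frequentist statistics


class TestROR:
    def test_closed_form_example(self):
        # frozen from oracle_ror(10, 90, 100, 9900)
        ror, lo, hi = ror_stats(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.559584639943105, rel=1e-9)
        assert hi == pytest.approx(21.764215824806342, rel=1e-9)

    def test_proportional_table_gives_unity_with_ci_straddling_one(self):
        ror, lo, hi = ror_stats(ContingencyTable(5, 50, 50, 500))
        assert ror == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_zero_cell_yields_undefined_marker(self):
        ror, lo, hi = ror_stats(ContingencyTable(0, 10, 10, 100))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    def test_strictly_increasing_in_a(self):
        values = [ror_stats(ContingencyTable(a, 50, 40, 900))[0] for a in range(1, 30)]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestPRR:
    def test_closed_form_example(self):
        # frozen from oracle_prr_chi2(20, 80, 100, 9800)
        prr, chi2 = prr_stats(ContingencyTable(20, 80, 100, 9800))
        assert prr == pytest.approx(19.8, rel=1e-9)
        assert chi2 == pytest.approx(285.3177524230156, rel=1e-9)

    def test_independence_floors_chi2_at_zero(self):
        prr, chi2 = prr_stats(ContingencyTable(5, 50, 50, 500))
        assert prr == pytest.approx(1.0)
        assert chi2 == 0.0

    def test_invalid_margins_raise(self):
        with pytest.raises(ValueError):
            prr_stats(ContingencyTable(3, 0, 0, 0))

    def test_zero_c_with_valid_margins_gives_undefined_prr(self):
        prr, chi2 = prr_stats(ContingencyTable(3, 0, 0, 1))
        assert math.isnan(prr)

    def test_rare_event_agreement_with_ror(self):
        """ROR -> PRR as the event rate under the drug goes to zero."""
        t = ContingencyTable(8, 2000, 40, 9000)  # a/(a+b) = 0.4% < 1%
        ror = ror_stats(t)[0]
        prr = prr_stats(t)[0]
        assert ror == pytest.approx(prr, rel=0.02)

    def test_strictly_increasing_in_a(self):
        values = [prr_stats(ContingencyTable(a, 50, 40, 900))[0] for a in range(1, 30)]
        assert all(x < y for x, y in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# MGPS / EBGM


class TestMGPS:
    def test_posterior_matches_quadrature_oracle(self):
        prior = MGPSPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        t = ContingencyTable(50, 50, 60, 2900)  # a=50, E ~ 3.6
        ebgm, ebgm05 = ebgm_stats(t, prior)
        o_ebgm, o_ebgm05 = oracle_ebgm(t.a, t.expected, prior)
        assert ebgm == pytest.approx(o_ebgm, rel=1e-3)
        assert ebgm05 == pytest.approx(o_ebgm05, rel=1e-3)
        assert ebgm05 < ebgm

    def test_observed_equals_expected_with_diffuse_prior_is_near_one(self):
        prior = MGPSPrior(1.0, 1.0, 1.0, 1.0, 0.5)
        t = ContingencyTable(100, 900, 900, 8100)  # a = E = 100
        assert t.a == pytest.approx(t.expected)
        ebgm, _ = ebgm_stats(t, prior)
        assert ebgm == pytest.approx(1.0, abs=0.05)

    def test_shrinkage_bounds_single_component_prior(self):
        """For a Gamma(α, β) prior the posterior arithmetic mean (α+a)/(β+E)
        lies between the prior mean and the raw ratio a/E, and the geometric
        mean EBGM sits just below it, within the Jensen gap exp(-1/(α+a))."""
        rng = np.random.default_rng(5)
        alpha = beta = 2.0
        prior = MGPSPrior(alpha, beta, alpha, beta, 1.0)
        for _ in range(200):
            a = int(rng.integers(0, 200))
            b, c, d = (int(x) for x in rng.integers(1, 500, 3))
            t = ContingencyTable(a, b, c, d)
            if t.expected <= 0 or a == 0:
                continue
            ebgm, _ = ebgm_stats(t, prior)
            e = t.expected
            post_mean = (alpha + a) / (beta + e)
            lo, hi = sorted((alpha / beta, a / e))
            assert lo - 1e-9 <= post_mean <= hi + 1e-9
            assert ebgm <= post_mean * (1 + 1e-12)
            assert ebgm >= post_mean * math.exp(-1.0 / (alpha + a)) * (1 - 1e-12)

    def test_ebgm_strictly_increasing_in_count(self):
        prior = MGPSPrior()
        values = [ebgm_stats(ContingencyTable(a, 200, 150, 5000), prior)[0]
                  for a in range(1, 40)]
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_prior_fit_recovers_simulated_hyperparameters(self):
        rng = np.random.default_rng(7)
        truth = MGPSPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        n = 4000
        e = np.exp(rng.uniform(np.log(0.5), np.log(50), n))
        comp = rng.random(n) < truth.w
        lam = np.where(
            comp,
            rng.gamma(truth.alpha1, 1 / truth.beta1, n),
            rng.gamma(truth.alpha2, 1 / truth.beta2, n),
        )
        a = rng.poisson(lam * e)
        fit = fit_mgps_prior(counts=a, expected=e)
        assert mixture_loglik(a, e, fit) >= mixture_loglik(a, e, truth) - 1.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            fit_mgps_prior([ContingencyTable(5, 5, 5, 5)])

    def test_no_signal_limit_concentrates_near_one(self):
        """Counts exactly equal to large expectations -> prior mass piles up at λ=1."""
        e = np.full(500, 400.0)
        a = e.copy()
        fit = fit_mgps_prior(counts=a, expected=e)
        # posterior-predictive geometric mean of λ for a typical pair ≈ 1
        t = ContingencyTable(400, 600, 400, 600)  # E = 400
        ebgm, _ = ebgm_stats(t, fit)
        assert ebgm == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# BCPNN / IC


class TestBCPNN:
    def test_independence_limit_is_zero_bits(self):
        t = ContingencyTable(1000, 9000, 9000, 81000)  # a = E = 1000
        ic, ic025 = bcpnn_stats(t)
        assert abs(ic) < 0.01
        assert ic025 < ic

    def test_large_count_matches_quantile_inversion_oracle(self):
        t = ContingencyTable(1896, 5837, 52000, 940267)
        ic, ic025 = bcpnn_stats(t)
        o_ic, o_ic025 = oracle_ic(t.a, t.expected)
        assert ic == pytest.approx(o_ic, abs=1e-9)
        assert ic025 == pytest.approx(o_ic025, abs=0.01)

    def test_zero_count_closed_form(self):
        # E = 10 exactly: rows (0, 40), cols (0+c). pick c so (a+b)(a+c)/N = 10
        t = ContingencyTable(0, 40, 15, 5)
        assert t.expected == pytest.approx(10.0)
        ic, _ = bcpnn_stats(t)
        assert ic == pytest.approx(math.log2(0.5 / 10.5))
        assert ic < 0

    def test_moment_variant_close_to_gamma_variant_for_large_tables(self):
        t = ContingencyTable(650, 7083, 250000, 1500000)
        ic_g, _ = bcpnn_stats(t, method="gamma")
        ic_m, ic025_m = bcpnn_stats(t, method="moment")
        assert ic_m == pytest.approx(ic_g, abs=0.1)
        assert ic025_m < ic_m


# ---------------------------------------------------------------------------
# thresholds, ranking, tables


def _stats(**kw):
    base = dict(event="e", a=100, ror=2.0, ror_lo=1.5, ror_hi=3.0, prr=1.0,
                chi2=1.0, ebgm=1.0, ebgm05=0.5, ic=0.1, ic025=-1.0)
    base.update(kw)
    return SignalStats(**base)


class TestEvaluate:
    def test_single_positive_rule_flags_combined_in_any_mode(self):
        # an ROR lower bound of 1.11 with a large count is a signal even when
        # the Bayesian statistics stay negative
        s = _stats(ror=1.17, ror_lo=1.11, ror_hi=1.24, a=1376)
        flags = evaluate(s, Thresholds())
        assert flags["ror"] and not flags["prr"] and not flags["mgps"] and not flags["bcpnn"]
        assert flags["combined"]

    def test_all_negative(self):
        s = _stats(ror_lo=0.9, prr=1.0, chi2=0.5, ebgm05=1.0, ic025=-0.5)
        assert not any(evaluate(s, Thresholds()).values())

    def test_prr_boundary_is_inclusive(self):
        s = _stats(ror_lo=0.5, prr=2.0, chi2=4.0, a=3, ebgm05=0.0, ic025=-1.0)
        flags = evaluate(s, Thresholds(min_a=3))
        assert flags["prr"] and flags["combined"]

    def test_undefined_statistics_evaluate_negative(self):
        s = _stats(ror=math.nan, ror_lo=math.nan, prr=math.nan, chi2=math.nan,
                   ebgm05=math.nan, ic025=math.nan)
        assert not any(evaluate(s, Thresholds()).values())

    def test_all_of_mode_requires_every_enabled_rule(self):
        s = _stats(ror_lo=1.5, prr=3.0, chi2=10.0, ebgm05=2.5, ic025=0.4)
        assert evaluate(s, Thresholds(mode="all"))["combined"]
        s2 = _stats(ror_lo=1.5, prr=3.0, chi2=10.0, ebgm05=1.5, ic025=0.4)
        assert not evaluate(s2, Thresholds(mode="all"))["combined"]


class TestTopK:
    def make(self, counts):
        return {
            ev: ContingencyTable(a, 100, 50, 1000) for ev, a in counts.items()
        }

    def test_orders_by_count_then_alphabetically(self):
        tables = self.make({"b_pt": 10, "a_pt": 10, "c_pt": 30})
        assert top_k_events(tables, 3) == ["c_pt", "a_pt", "b_pt"]

    def test_k_larger_than_event_count_returns_all(self):
        tables = self.make({"a": 1, "b": 2})
        assert top_k_events(tables, 10) == ["b", "a"]

    def test_agrees_with_full_sort_oracle(self, rng):
        counts = {f"pt_{i:03d}": int(rng.integers(0, 50)) for i in range(60)}
        tables = self.make(counts)
        oracle = [ev for ev, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert top_k_events(tables, 25) == oracle[:25]


def _case(pid, drug, pts, role="PS"):
    return CaseReport(
        primaryid=pid, caseid=pid, fda_dt=20200101,
        drugs=[DrugEntry(drug, role)], reactions=sorted(set(pts)),
    )


class TestBuildTables:
    def test_exhaustive_count_tiny_example(self):
        target = [_case("1", "vismodegib", ["X"])]
        others = [_case(str(i), "other", ["Y"]) for i in range(2, 11)]
        tables = build_tables(target, ["vismodegib"], background=target + others)
        assert tables["X"] == ContingencyTable(1, 0, 0, 9)
        # event absent from target reports still gets a table
        assert tables["Y"] == ContingencyTable(0, 1, 9, 0)

    def test_margins_conserved_across_events(self, small_db):
        reports, target = small_db
        tables = build_tables(target, ["vismodegib"], background=reports)
        for t in tables.values():
            assert t.n == len(reports)
            assert t.a + t.b == len(target)

    def test_a_plus_c_equals_event_report_count(self, small_db):
        reports, target = small_db
        tables = build_tables(target, ["vismodegib"], background=reports)
        for ev, t in tables.items():
            direct = sum(1 for r in reports if ev in r.reactions)
            assert t.a + t.c == direct

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            build_tables([], ["x"], background=[])
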