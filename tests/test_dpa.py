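"""Disproportionality statistics against independent oracles, and the
consensus classification thresholds."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.stats import chi2_contingency

from faers_signals.contingency import ContingencyTable
from faers_signals.dpa import (
    ALGORITHMS,
    BcpnnPriors,
    MgpsHyperparams,
    SignalStats,
    bcpnn_ic,
    classify,
    mgps_fit,
    mgps_score,
    overlap_counts,
    prr_chi2,
    ror_stats,
    simplified_ebgm,
)

from conftest import random_tables


# ---------------------------------------------------------------------------
# ROR / PRR / chi-square
# ---------------------------------------------------------------------------

def test_ror_symmetric_table_is_one_with_log_symmetric_ci():
    ror, lo, hi = ror_stats(ContingencyTable(10, 10, 10, 10))
    assert ror == 1.0
    assert lo * hi == pytest.approx(1.0)


def test_ror_zero_cell_is_undefined_not_corrected():
    assert all(math.isnan(v) for v in ror_stats(ContingencyTable(0, 10, 10, 10)))


def test_ror_bounds_match_independent_wald_oracle():
    rng = np.random.default_rng(2)
    for t in random_tables(rng, 100):
        ror, lo, hi = ror_stats(t)
        log_ror = math.log(t.a) + math.log(t.d) - math.log(t.b) - math.log(t.c)
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        assert lo == pytest.approx(math.exp(log_ror - 1.96 * se), rel=1e-12)
        assert hi == pytest.approx(math.exp(log_ror + 1.96 * se), rel=1e-12)


def test_prr_one_and_chi2_zero_at_exact_independence():
    prr, chi2 = prr_chi2(ContingencyTable(5, 45, 95, 855))
    assert prr == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-12)


def test_chi2_matches_cellwise_oracle_and_scipy():
    rng = np.random.default_rng(3)
    for t in random_tables(rng, 50):
        _, chi2 = prr_chi2(t)
        obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        cellwise = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(cellwise, rel=1e-10)
        assert chi2 == pytest.approx(
            chi2_contingency(obs, correction=False).statistic, rel=1e-10
        )


def test_doubling_cells_doubles_chi2_and_fixes_prr():
    t = ContingencyTable(8, 40, 30, 700)
    t2 = ContingencyTable(16, 80, 60, 1400)
    prr, chi2 = prr_chi2(t)
    prr2, chi22 = prr_chi2(t2)
    assert prr2 == pytest.approx(prr)
    assert chi22 == pytest.approx(2 * chi2)


def test_yates_correction_reduces_chi2():
    t = ContingencyTable(8, 40, 30, 700)
    assert prr_chi2(t, yates=True)[1] < prr_chi2(t)[1]


def test_ror_dominates_prr_above_one():
    """Odds-ratio dominance: all cells > 0 and ror > 1 implies ror > prr > 1."""
    rng = np.random.default_rng(4)
    seen = 0
    for t in random_tables(rng, 200):
        ror, _, _ = ror_stats(t)
        prr, _ = prr_chi2(t)
        if ror > 1:
            seen += 1
            assert ror > prr > 1
    assert seen > 20


def test_monotonicity_in_a_with_margins_fixed():
    """Moving one count from b,c into a,d (margins fixed) raises every statistic."""
    base = ContingencyTable(10, 90, 50, 850)
    more = ContingencyTable(11, 89, 49, 851)
    theta = MgpsHyperparams(*np.array([0.5, 0.5, 2.0, 2.0, 0.4]))
    assert ror_stats(more)[0] > ror_stats(base)[0]
    assert prr_chi2(more)[0] > prr_chi2(base)[0]
    assert bcpnn_ic(more)[0] > bcpnn_ic(base)[0]
    assert mgps_score(more, theta)[0] > mgps_score(base, theta)[0]


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

def mc_ic_oracle(t, priors=BcpnnPriors(), ndraw=200_000, seed=0):
    """Monte-Carlo posterior: independent Beta draws for the joint cell and
    the two margins under the same conjugate priors."""
    rng = np.random.default_rng(seed)
    g = priors.gamma(t)
    n, a, ab, ac = t.n, t.a, t.a + t.b, t.a + t.c
    p11 = rng.beta(a + priors.gamma11, n - a + g - priors.gamma11, ndraw)
    p1 = rng.beta(ab + priors.alpha1, n - ab + priors.alpha - priors.alpha1, ndraw)
    p2 = rng.beta(ac + priors.beta1, n - ac + priors.beta - priors.beta1, ndraw)
    return float(np.mean(np.log2(p11 / (p1 * p2))))


def test_ic_negative_when_no_co_reporting():
    ic, _, ic025 = bcpnn_ic(ContingencyTable(0, 3, 3, 3))
    assert ic < 0
    assert ic025 < ic


def test_ic_approaches_zero_at_large_n_independence():
    prev = None
    for scale in (10, 100, 1000):
        t = ContingencyTable(scale, 9 * scale, 9 * scale, 81 * scale)
        ic = bcpnn_ic(t)[0]
        assert t.a == pytest.approx(t.expected)
        if prev is not None:
            assert abs(ic) < abs(prev)
        prev = ic
    assert abs(prev) < 0.01


def test_ic_matches_monte_carlo_posterior_oracle():
    rng = np.random.default_rng(8)
    for t in random_tables(rng, 12, a_min=10, a_max=50):
        ic = bcpnn_ic(t)[0]
        assert abs(ic - mc_ic_oracle(t)) < 0.1


def test_ic025_is_ic_minus_two_sd():
    t = ContingencyTable(12, 88, 40, 900)
    ic, var, ic025 = bcpnn_ic(t)
    assert ic025 == pytest.approx(ic - 2 * math.sqrt(var))
    assert ic025 < ic


# ---------------------------------------------------------------------------
# MGPS
# ---------------------------------------------------------------------------

class _Pair:
    """Minimal (a, E) carrier accepted by the MGPS fitter."""

    def __init__(self, a, e):
        self.a = int(a)
        self.expected = float(e)


def simulate_pairs(theta: MgpsHyperparams, n: int, seed: int):
    rng = np.random.default_rng(seed)
    comp1 = rng.random(n) < theta.p_mix
    lam = np.where(
        comp1,
        rng.gamma(theta.alpha1_g, 1 / theta.beta1_g, n),
        rng.gamma(theta.alpha2_g, 1 / theta.beta2_g, n),
    )
    e = rng.lognormal(math.log(20.0), 1.0, n)
    return [_Pair(a, ei) for a, ei in zip(rng.poisson(lam * e), e)]


def canonical(theta: MgpsHyperparams) -> np.ndarray:
    """Order mixture components by ascending mean (labels are arbitrary)."""
    comps = sorted(
        [
            (theta.alpha1_g / theta.beta1_g, theta.alpha1_g, theta.beta1_g, theta.p_mix),
            (theta.alpha2_g / theta.beta2_g, theta.alpha2_g, theta.beta2_g, 1 - theta.p_mix),
        ]
    )
    (_, a1, b1, p1), (_, a2, b2, _) = comps
    return np.array([a1, b1, a2, b2, p1])


def test_mgps_recovers_known_hyperparameters():
    true = MgpsHyperparams(2.0, 2.0, 3.0, 0.3, 0.7)
    fit = mgps_fit(simulate_pairs(true, 5000, seed=7))
    rel = np.abs(canonical(fit) - canonical(true)) / canonical(true)
    assert np.all(rel < 0.15), rel


def test_mgps_null_data_concentrates_near_lambda_one():
    """If every a equals its expected count, the fitted prior concentrates
    near lambda = 1: every component carrying real weight has mean in
    [0.8, 1.25] and at least 95% of prior mass lies in that interval (a
    component whose weight collapses to ~0 has an unidentified mean)."""
    rng = np.random.default_rng(9)
    e = rng.lognormal(math.log(30.0), 0.8, 2000)
    pairs = [_Pair(round(ei), ei) for ei in e]
    fit = mgps_fit(pairs)
    comps = [
        (fit.p_mix, fit.alpha1_g, fit.beta1_g),
        (1 - fit.p_mix, fit.alpha2_g, fit.beta2_g),
    ]
    for w, shape, rate in comps:
        if w >= 0.01:
            assert 0.8 <= shape / rate <= 1.25
    mass = sum(
        w * (sps.gamma.cdf(1.25, shape, scale=1 / rate) - sps.gamma.cdf(0.8, shape, scale=1 / rate))
        for w, shape, rate in comps
    )
    assert mass > 0.95


def test_mgps_fit_invariant_to_table_order():
    true = MgpsHyperparams(1.0, 1.0, 4.0, 0.5, 0.5)
    pairs = simulate_pairs(true, 500, seed=10)
    a = mgps_fit(pairs)
    b = mgps_fit(pairs[::-1])
    assert np.allclose(a.as_array(), b.as_array(), rtol=1e-6)


def test_mgps_point_mass_prior_dominates():
    theta = MgpsHyperparams(1e4, 1e4, 1e4 + 1, 1e4 + 1, 0.5)  # both means ~1, tiny variance
    for a in (1, 5, 40):
        ebgm, eb05 = mgps_score(ContingencyTable(a, 50, 50, 1000), theta)
        assert ebgm == pytest.approx(1.0, abs=0.05)


def test_mgps_shrinks_toward_prior_and_orders_quantiles():
    theta = MgpsHyperparams(0.5, 0.5, 2.0, 2.0, 0.3)  # prior means 1 and 1
    t = ContingencyTable(20, 80, 50, 2000)
    rrr = t.a / t.expected
    ebgm, eb05 = mgps_score(t, theta)
    assert 0 < eb05 < ebgm < rrr  # shrinkage toward the prior mean


def test_mgps_shrinkage_vanishes_asymptotically():
    theta = MgpsHyperparams(0.5, 0.5, 2.0, 2.0, 0.3)
    ratios = []
    for scale in (1, 10, 100):
        t = ContingencyTable(20 * scale, 80 * scale, 50 * scale, 2000 * scale)
        ebgm, _ = mgps_score(t, theta)
        ratios.append(ebgm / (t.a / t.expected))
    assert ratios == sorted(ratios)
    assert ratios[-1] == pytest.approx(1.0, abs=0.02)


def test_eb05_matches_monte_carlo_posterior_quantile():
    theta = MgpsHyperparams(1.2, 0.8, 3.0, 1.0, 0.35)
    rng = np.random.default_rng(12)
    for t in [ContingencyTable(8, 60, 30, 900), ContingencyTable(25, 200, 90, 5000)]:
        ebgm, eb05 = mgps_score(t, theta)
        # independent posterior-weight computation + 1e6 draws
        a, e = t.a, t.expected
        w1 = theta.p_mix * sps.nbinom.pmf(a, theta.alpha1_g, theta.beta1_g / (theta.beta1_g + e))
        w2 = (1 - theta.p_mix) * sps.nbinom.pmf(a, theta.alpha2_g, theta.beta2_g / (theta.beta2_g + e))
        q1 = w1 / (w1 + w2)
        n = 1_000_000
        comp1 = rng.random(n) < q1
        draws = np.where(
            comp1,
            rng.gamma(theta.alpha1_g + a, 1 / (theta.beta1_g + e), n),
            rng.gamma(theta.alpha2_g + a, 1 / (theta.beta2_g + e), n),
        )
        mc_q05 = np.quantile(draws, 0.05)
        assert eb05 == pytest.approx(mc_q05, rel=5e-3)
        assert math.exp(np.mean(np.log(draws))) == pytest.approx(ebgm, rel=5e-3)


def test_simplified_mode_is_rrr_with_wald_style_lower_bound():
    t = ContingencyTable(29, 1117, 173, 51000)
    ebgm, eb05 = simplified_ebgm(t)
    assert ebgm == pytest.approx(t.a / t.expected)
    ror, lo, _ = ror_stats(t)
    assert eb05 / ebgm == pytest.approx(lo / ror, rel=1e-12)


# ---------------------------------------------------------------------------
# Classification and overlap
# ---------------------------------------------------------------------------

def make_stats(**kw) -> SignalStats:
    base = dict(term="X", level="PT", a=10, ror_lo=2.0, prr=3.0, chi2=10.0, ic025=1.0, eb05=3.0)
    base.update(kw)
    return SignalStats(**base)


class TestClassify:
    def test_ror_boundary_is_strict(self):
        assert classify(make_stats(ror_lo=1.0)).flags["ROR"] is False
        assert classify(make_stats(ror_lo=1.0 + 1e-9)).flags["ROR"] is True

    def test_prr_boundary_is_non_strict(self):
        assert classify(make_stats(prr=2.0, chi2=4.0)).flags["PRR"] is True
        assert classify(make_stats(prr=2.0, chi2=3.999)).flags["PRR"] is False
        assert classify(make_stats(prr=1.999, chi2=4.0)).flags["PRR"] is False

    def test_ic025_boundary_is_strict(self):
        assert classify(make_stats(ic025=0.0)).flags["BCPNN"] is False
        assert classify(make_stats(ic025=1e-9)).flags["BCPNN"] is True

    def test_eb05_boundary_is_strict(self):
        assert classify(make_stats(eb05=2.0)).flags["EBGM"] is False
        assert classify(make_stats(eb05=2.0 + 1e-9)).flags["EBGM"] is True

    def test_consensus_is_and_of_all_four(self):
        s = classify(make_stats())
        assert s.consensus is True
        s = classify(make_stats(eb05=1.0))
        assert s.flags["ROR"] and s.flags["PRR"] and s.flags["BCPNN"]
        assert s.consensus is False

    def test_ineligible_terms_get_all_false_flags(self):
        s = classify(make_stats(a=2))
        assert s.eligible is False
        assert not any(s.flags.values())
        assert s.consensus is False

    def test_nan_statistics_never_fire(self):
        s = classify(make_stats(ror_lo=float("nan"), prr=float("nan"), chi2=float("nan")))
        assert s.flags["ROR"] is False and s.flags["PRR"] is False


class TestOverlap:
    def _stats(self, flag_sets):
        out = []
        for term, flags in flag_sets.items():
            s = make_stats(term=term)
            s.flags = {alg: alg in flags for alg in ALGORITHMS}
            s.consensus = all(s.flags.values())
            out.append(s)
        return out

    def test_disjoint_sets_have_empty_intersections(self):
        stats = self._stats({"A": {"ROR"}, "B": {"PRR"}, "C": {"BCPNN"}, "D": {"EBGM"}})
        counts = overlap_counts(stats)
        assert counts["ROR"] == counts["PRR"] == 1
        assert counts["ROR&PRR&BCPNN&EBGM"] == 0
        assert counts["consensus"] == 0

    def test_identical_sets_intersect_fully(self):
        stats = self._stats({t: set(ALGORITHMS) for t in "ABC"})
        counts = overlap_counts(stats)
        assert counts["ROR"] == counts["ROR&PRR&BCPNN&EBGM"] == counts["consensus"] == 3

    def test_random_flags_match_set_algebra(self):
        rng = np.random.default_rng(13)
        flag_sets = {
            f"T{i}": {alg for alg in ALGORITHMS if rng.random() < 0.5} for i in range(40)
        }
        counts = overlap_counts(self._stats(flag_sets))
        sets = {alg: {t for t, f in flag_sets.items() if alg in f} for alg in ALGORITHMS}
        assert counts["ROR&BCPNN"] == len(sets["ROR"] & sets["BCPNN"])
        assert counts["PRR&BCPNN&EBGM"] == len(sets["PRR"] & sets["BCPNN"] & sets["EBGM"])
        assert counts["ROR&PRR&BCPNN&EBGM"] == len(
            sets["ROR"] & sets["PRR"] & sets["BCPNN"] & sets["EBGM"]
        )
        assert counts["consensus"] == counts["ROR&PRR&BCPNN&EBGM"]
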