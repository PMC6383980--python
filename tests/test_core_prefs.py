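"""The expected-utility core: utilities, certainty equivalents, analytics.

Deterministic analytics are cross-checked against independent oracles:
adaptive quadrature (scipy.integrate.quad) for E[V] and, for single-crossing
pairs, the closed-form route Pr Core = BetaCDF(root) using the monotonicity
of the certainty equivalent in the risk parameter.
"""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

import breut
from breut import (
    CorePrefs,
    LotteryPair,
    ValidationError,
    ce_difference,
    certainty_equivalent,
    pair_analytics,
    parse_lottery,
    parse_pair,
    sample_r,
    utility,
)


class TestUtility:
    def test_risk_neutral_identity(self):
        assert utility(40, 0.0) == 40.0

    def test_zero_outcome_normalisation(self):
        for r in (-0.5, 0.0, 0.5, 0.99):
            assert utility(0.0, r) == 0.0

    def test_square_root_case(self):
        assert utility(40, 0.5) == pytest.approx(math.sqrt(40), abs=1e-12)

    def test_r_at_or_above_one_rejected(self):
        with pytest.raises(ValidationError):
            utility(10, 1.0)


class TestCertaintyEquivalent:
    def test_expected_value_under_linearity(self, lottery_b):
        assert certainty_equivalent(lottery_b, 0.0) == pytest.approx(32.0, abs=1e-12)

    def test_closed_form_at_r_half(self, lottery_b):
        # (0.8 * sqrt(40))**2 = 0.64 * 40
        assert certainty_equivalent(lottery_b, 0.5) == pytest.approx(25.6, abs=1e-10)

    def test_sure_amount_invariant_in_r(self):
        sure = parse_lottery("30:1")
        for r in (-0.9, 0.0, 0.37, 0.99):
            assert certainty_equivalent(sure, r) == 30.0

    def test_strictly_decreasing_in_r_for_risky_lottery(self, lottery_b):
        grid = np.linspace(-0.8, 0.95, 200)
        ces = certainty_equivalent(lottery_b, grid)
        assert np.all(np.diff(ces) < 0)

    def test_vectorised_matches_scalar(self, lottery_b):
        grid = np.linspace(-0.5, 0.9, 7)
        vec = certainty_equivalent(lottery_b, grid)
        assert vec == pytest.approx([certainty_equivalent(lottery_b, r) for r in grid])


class TestCEDifference:
    def test_risk_neutral_value(self, pair_30_vs_b):
        assert ce_difference(pair_30_vs_b, 0.0) == pytest.approx(-2.0, abs=1e-12)

    def test_identical_lotteries_zero(self):
        pair = parse_pair("30:1", "30:1")
        for r in (-0.3, 0.0, 0.6):
            assert ce_difference(pair, r) == 0.0

    def test_common_scale_pair_always_positive(self):
        # (51,.5;0,.5) vs (50,.5;0,.5): difference is 0.5**(1/(1-r)) > 0
        pair = parse_pair("51:0.5,0:0.5", "50:0.5,0:0.5")
        grid = np.linspace(-0.9, 0.95, 100)
        v = ce_difference(pair, grid)
        assert np.all(v > 0)
        assert v == pytest.approx(0.5 ** (1.0 / (1.0 - grid)), rel=1e-10)


class TestCorePrefs:
    def test_support_must_stay_below_one(self):
        with pytest.raises(ValidationError, match="beta_range"):
            CorePrefs(0.6, 1.0)
        CorePrefs(0.45, 1.0)  # 0.45 + 0.5 < 1: fine

    def test_degenerate_core_is_point_mass(self, rng):
        core = CorePrefs(0.3, 0.0)
        draws = sample_r(core, rng, size=100)
        assert np.all(draws == 0.3)

    def test_sampler_moments(self):
        core = CorePrefs(0.35, 1.0)
        draws = sample_r(core, np.random.default_rng(11), size=1_000_000)
        sd = math.sqrt(1.0 / 28.0)  # Beta(3,3) variance is 1/28
        assert abs(draws.mean() - 0.35) < 3 * sd / 1000
        assert draws.var() == pytest.approx(1.0 / 28.0, rel=0.01)
        lo, hi = core.support
        assert draws.min() >= lo and draws.max() <= hi


def _pr_core_single_crossing(pair, core):
    """Oracle: CE is decreasing in r, so V crosses zero at most once."""
    lo, hi = core.support
    f = lambda r: ce_difference(pair, r)
    v_lo, v_hi = f(lo), f(hi)
    if v_lo > 0 and v_hi > 0:
        return 1.0
    if v_lo < 0 and v_hi < 0:
        return 0.0
    root = optimize.brentq(f, lo, hi, xtol=1e-13)
    mass_below = stats.beta(3, 3).cdf((root - lo) / core.beta_range)
    return mass_below if v_lo > 0 else 1.0 - mass_below


def _e_v_quad(pair, core):
    lo, _ = core.support
    return integrate.quad(
        lambda t: ce_difference(pair, lo + core.beta_range * t) * 30 * t**2 * (1 - t) ** 2,
        0.0,
        1.0,
        epsabs=1e-10,
    )[0]


class TestPairAnalytics:
    @pytest.mark.parametrize("sure_amount", [20, 24, 28, 30, 32])
    def test_against_independent_oracles(self, sure_amount, lottery_b, core_035):
        pair = LotteryPair(parse_lottery(f"{sure_amount}:1"), lottery_b)
        an = pair_analytics(pair, core_035)
        assert an.pr_core == pytest.approx(_pr_core_single_crossing(pair, core_035), abs=1e-6)
        assert an.e_v == pytest.approx(_e_v_quad(pair, core_035), abs=1e-6)

    def test_sure_28_row_values(self, lottery_b, core_035):
        # frozen from the quadrature oracle: E[CE_B] = 27.59072513433271
        pair = LotteryPair(parse_lottery("28:1"), lottery_b)
        an = pair_analytics(pair, core_035)
        assert an.e_v == pytest.approx(28 - 27.59072513433271, abs=1e-6)
        assert an.pr_core == pytest.approx(0.45, abs=0.01)
        assert an.pr_lim == 1.0

    def test_dominating_pair_core_probability_is_one(self, core_023):
        pair = parse_pair("60:0.5,0:0.5", "50:0.5,0:0.5")
        an = pair_analytics(pair, core_023)
        assert an.pr_core == 1.0
        assert an.pr_lim == 1.0

    def test_identical_lotteries(self, core_035):
        an = pair_analytics(parse_pair("30:1", "30:1"), core_035)
        assert 0.0 <= an.pr_core <= 1.0
        assert an.e_v == 0.0
        assert an.pr_lim == 0.5

    def test_point_mass_core(self):
        pair = parse_pair("30:1", "40:0.8,0:0.2")
        an = pair_analytics(pair, CorePrefs(0.0, 0.0))
        assert an.e_v == pytest.approx(-2.0, abs=1e-12)
        assert an.pr_core == 0.0
        assert an.pr_lim == 0.0

    def test_multiple_sign_changes_handled(self):
        # a sure amount equal to the risk-neutral CE: V crosses exactly at
        # r = 0, an interior grid point flanked by opposite signs
        pair = parse_pair("32:1", "40:0.8,0:0.2")
        an = pair_analytics(pair, CorePrefs(0.35, 1.0))
        assert an.pr_core == pytest.approx(_pr_core_single_crossing(pair, CorePrefs(0.35, 1.0)), abs=1e-6)
        assert 0 < an.pr_core < 1

    def test_e_v_additivity_over_lottery_triples(self, core_035, rng):
        for _ in range(10):
            x = breut.random_pair_generator(rng, branch_counts=(1, 3))
            y = breut.random_pair_generator(rng, branch_counts=(1, 3))
            ab = pair_analytics(LotteryPair(x.a, y.a), core_035).e_v
            bc = pair_analytics(LotteryPair(y.a, x.b), core_035).e_v
            ac = pair_analytics(LotteryPair(x.a, x.b), core_035).e_v
            assert ab + bc == pytest.approx(ac, abs=1e-6)

    def test_e_v_scales_with_payoff_gap(self, core_023):
        wide = pair_analytics(parse_pair("60:0.5,0:0.5", "50:0.5,0:0.5"), core_023).e_v
        narrow = pair_analytics(parse_pair("51:0.5,0:0.5", "50:0.5,0:0.5"), core_023).e_v
        assert wide == pytest.approx(10 * narrow, rel=1e-9)

    def test_monte_carlo_agrees_with_quadrature(self, core_035, pair_30_vs_b):
        draws = sample_r(core_035, np.random.default_rng(5), size=1_000_000)
        v = ce_difference(pair_30_vs_b, draws)
        an = pair_analytics(pair_30_vs_b, core_035)
        p_hat = float(np.mean(v > 0))
        se_p = math.sqrt(p_hat * (1 - p_hat) / v.size)
        assert abs(p_hat - an.pr_core) < 4 * se_p
        se_v = v.std(ddof=1) / math.sqrt(v.size)
        assert abs(v.mean() - an.e_v) < 4 * se_v
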