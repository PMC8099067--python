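"""Triangular primitives, Monte Carlo engine and the analytic oracle.

The triangular CDF/quantile pair is checked against scipy.stats.triang,
and the convolution oracle against brute-force numeric integration — both
independent of the inverse-transform implementation under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import triang

from spbudget.engine import (
    InvalidScenarioError,
    analytic_net_distribution,
    empirical_cdf,
    sample_triangular,
    simulate_net_effect,
    tri_cdf,
    tri_pdf,
    tri_quantile,
)
from spbudget.model import CashFlowItem, Scenario, SimConfig, TriangularEstimate

# Brute-force oracle value: P(benefit - cost < 0) for benefit Tri(0, 0.15,
# 0.30) vs cost Tri(0, 0.08, 0.50), by adaptive quadrature of
# f_B(b) * (1 - F_C(b)).  Frozen from scipy.integrate.quad (abs err < 1e-8).
SOCIALISATION_P_LOSS = 0.5966754831

ESTIMATES = [
    TriangularEstimate(0.0, 1.0, 2.0),
    TriangularEstimate(0.0, 0.08, 0.50),
    TriangularEstimate(0.0, 0.15, 0.30),
    TriangularEstimate(1.20, 1.60, 2.00),
    TriangularEstimate(0.0, 0.0, 1.0),   # mode at lower endpoint
    TriangularEstimate(0.0, 1.0, 1.0),   # mode at upper endpoint
]


def _scipy_tri(e):
    return triang((e.mode - e.low) / (e.high - e.low), loc=e.low, scale=e.high - e.low)


class TestTriangularPrimitives:
    @pytest.mark.parametrize("e", ESTIMATES, ids=str)
    def test_cdf_and_pdf_match_scipy(self, e):
        x = np.linspace(e.low - 0.5, e.high + 0.5, 301)
        ref = _scipy_tri(e)
        np.testing.assert_allclose(tri_cdf(e, x), ref.cdf(x), atol=1e-12)
        np.testing.assert_allclose(tri_pdf(e, x), ref.pdf(x), atol=1e-9)

    @pytest.mark.parametrize("e", ESTIMATES, ids=str)
    def test_quantile_matches_scipy(self, e):
        p = np.linspace(0, 1, 201)
        np.testing.assert_allclose(tri_quantile(e, p), _scipy_tri(e).ppf(p), atol=1e-12)

    def test_cdf_worked_values(self):
        assert tri_cdf(TriangularEstimate(0, 1, 2), 1.0) == pytest.approx(0.5)
        # F(mode) = (mode - low) / (high - low)
        assert tri_cdf(TriangularEstimate(0, 0.08, 0.50), 0.08) == pytest.approx(0.16)
        assert tri_quantile(TriangularEstimate(0, 0.08, 0.50), 0.16) == pytest.approx(0.08)

    def test_point_mass_is_a_step_function(self):
        e = TriangularEstimate(0.5, 0.5, 0.5)
        assert tri_cdf(e, 0.49) == 0.0
        assert tri_cdf(e, 0.5) == 1.0
        assert tri_quantile(e, 0.3) == 0.5
        assert np.all(sample_triangular(e, 10, np.random.default_rng(0)) == 0.5)

    @given(
        a=st.floats(-5, 5), da=st.floats(0.01, 5), db=st.floats(0.01, 5),
        p=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_quantile_is_inverse_of_cdf(self, a, da, db, p):
        e = TriangularEstimate(a, a + da, a + da + db)
        assert tri_cdf(e, tri_quantile(e, p)) == pytest.approx(p, abs=1e-12)

    def test_quantile_hits_support_bounds(self):
        e = TriangularEstimate(0, 0.08, 0.50)
        assert tri_quantile(e, 0.0) == e.low
        assert tri_quantile(e, 1.0) == e.high

    def test_quantile_rejects_probabilities_outside_unit_interval(self):
        with pytest.raises(ValueError):
            tri_quantile(TriangularEstimate(0, 1, 2), 1.5)


class TestSampling:
    def test_reproducible_for_fixed_seed(self):
        e = TriangularEstimate(0, 1, 2)
        a = sample_triangular(e, 100, np.random.default_rng(42))
        b = sample_triangular(e, 100, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_samples_within_support_and_mean_converges(self):
        e = TriangularEstimate(0, 1, 2)
        x = sample_triangular(e, 100_000, np.random.default_rng(7))
        assert x.min() >= 0 and x.max() <= 2
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - e.mean) < 3 * se  # mean = (low + mode + high) / 3


class TestSimulation:
    def test_certain_loss_scenarios(self, large_groups, pheromones):
        for s in (large_groups, pheromones):
            r = simulate_net_effect(s, SimConfig(n_samples=500, seed=3))
            assert r.prob_loss == 1.0 and r.prob_nonneg == 0.0

    def test_socialisation_loss_probability_near_oracle(self, socialisation):
        r = simulate_net_effect(socialisation, SimConfig(n_samples=500, seed=3))
        # 500-draw binomial SE is ~2.2 percentage points
        assert r.prob_loss == pytest.approx(SOCIALISATION_P_LOSS, abs=3 * 0.022)

    def test_complement_probabilities_sum_to_one(self, socialisation):
        r = simulate_net_effect(socialisation, SimConfig(n_samples=501, seed=9))
        assert r.prob_loss + r.prob_nonneg == 1.0

    @pytest.mark.parametrize("mode", ["components", "totals"])
    def test_samples_within_analytic_support(self, fixtures, mode):
        for s in fixtures.values():
            lo, hi = s.support()
            r = simulate_net_effect(s, SimConfig(2000, seed=11, aggregate_mode=mode))
            assert r.sample_min >= lo - 1e-12 and r.sample_max <= hi + 1e-12

    def test_scale_equivariance(self, socialisation):
        k = 3.7
        cfg = SimConfig(n_samples=4000, seed=5)
        r1 = simulate_net_effect(socialisation, cfg)
        rk = simulate_net_effect(socialisation.scaled(k), cfg)
        np.testing.assert_allclose(rk.samples, k * r1.samples, atol=1e-12)
        assert rk.prob_loss == r1.prob_loss

    def test_benefit_only_scenario_never_loses(self):
        s = Scenario("win", "benefits only", (
            CashFlowItem("b", "benefit", TriangularEstimate(0, 1, 2)),))
        r = simulate_net_effect(s, SimConfig(1000, seed=2))
        assert r.prob_loss == 0.0

    def test_invalid_scenario_rejected_with_messages(self):
        s = Scenario("bad", "bad", (
            CashFlowItem("x", "cost", TriangularEstimate(1.0, 0.5, 0.7)),))
        with pytest.raises(InvalidScenarioError) as err:
            simulate_net_effect(s, SimConfig())
        assert any("ordering" in m for m in err.value.messages)

    def test_totals_mode_uses_summed_bounds_support(self, pheromones):
        r = simulate_net_effect(pheromones, SimConfig(2000, seed=13, aggregate_mode="totals"))
        assert r.prob_loss == 1.0
        assert r.sample_min >= -0.50 - 1e-12 and r.sample_max <= -0.02 + 1e-12


class TestEmpiricalCdf:
    def test_counting(self):
        from spbudget.engine import SimulationResult
        r = SimulationResult("s", np.array([-1.0, 0.0, 1.0]), SimConfig(3, seed=0))
        curve = empirical_cdf(r)
        assert curve.at(0.0) == pytest.approx(2 / 3)
        assert curve.probability[-1] == 1.0

    def test_constant_samples_single_step(self):
        r = simulate_net_effect(
            Scenario("s", "s", (CashFlowItem("b", "benefit", TriangularEstimate(1, 1, 1)),)),
            SimConfig(5, seed=0))
        curve = empirical_cdf(r)
        assert np.all(curve.grid == 1.0) and curve.probability[-1] == 1.0

    def test_cdf_is_monotone_with_unit_mass(self, socialisation):
        r = simulate_net_effect(socialisation, SimConfig(500, seed=21))
        curve = empirical_cdf(r)
        assert np.all(np.diff(curve.probability) >= 0)
        assert np.all(np.diff(curve.grid) >= 0)
        assert curve.probability[-1] == 1.0


class TestAnalyticOracle:
    def test_single_item_identity(self):
        e = TriangularEstimate(0, 1, 2)
        s = Scenario("one", "one", (CashFlowItem("b", "benefit", e),))
        curve = analytic_net_distribution(s, resolution=1e-3)
        x = np.linspace(-0.5, 2.5, 101)
        np.testing.assert_allclose(
            [curve.at(v) for v in x], tri_cdf(e, x), atol=2e-3)

    def test_socialisation_loss_probability(self, socialisation):
        curve = analytic_net_distribution(socialisation, resolution=1e-3)
        assert curve.at(0.0) == pytest.approx(SOCIALISATION_P_LOSS, abs=2e-3)

    def test_refining_resolution_converges(self, socialisation):
        coarse = analytic_net_distribution(socialisation, resolution=5e-3).at(0.0)
        fine = analytic_net_distribution(socialisation, resolution=2e-4).at(0.0)
        assert abs(fine - SOCIALISATION_P_LOSS) < abs(coarse - SOCIALISATION_P_LOSS) + 1e-6

    def test_large_groups_support(self, large_groups):
        curve = analytic_net_distribution(large_groups, resolution=1e-3)
        assert curve.grid[0] == pytest.approx(-3.15, abs=5e-3)
        assert curve.grid[-1] == pytest.approx(-0.90, abs=5e-3)
        assert curve.at(0.0) == 1.0

    def test_oracle_against_independent_quadrature(self, pheromones):
        # brute force: P(net < t) = E[F_B(t + C1 + C2)] by tensor-product
        # Gauss-Legendre quadrature over the two cost densities (the
        # integrand is continuous, so a fixed 400-node rule is ample)
        b = _scipy_tri(TriangularEstimate(0.0, 0.15, 0.30))
        c1 = _scipy_tri(TriangularEstimate(0.31, 0.39, 0.46))
        c2 = _scipy_tri(TriangularEstimate(0.01, 0.03, 0.04))
        nodes, weights = np.polynomial.legendre.leggauss(400)

        def affine(lo, hi):
            return (hi - lo) / 2 * nodes + (hi + lo) / 2, (hi - lo) / 2 * weights

        x1, w1 = affine(0.31, 0.46)
        x2, w2 = affine(0.01, 0.04)

        def p_below(t):
            inner = b.cdf(t + x1[:, None] + x2[None, :])
            return float(w1 @ (c1.pdf(x1)[:, None] * c2.pdf(x2)[None, :] * inner) @ w2)

        curve = analytic_net_distribution(pheromones, resolution=1e-3)
        for t in (-0.40, -0.25, -0.10):
            assert curve.at(t) == pytest.approx(p_below(t), abs=2e-3)

    def test_monte_carlo_agrees_with_oracle(self, fixtures):
        # dual-route check at n = 100,000 within 3 binomial standard errors
        for s in fixtures.values():
            p = analytic_net_distribution(s, resolution=1e-3).at(0.0)
            r = simulate_net_effect(s, SimConfig(100_000, seed=17))
            se = np.sqrt(p * (1 - p) / 100_000)
            assert abs(r.prob_loss - p) <= max(3 * se, 1e-12)
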