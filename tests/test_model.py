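"""Core model: mating function, normaliser, pair density, likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import matefit as mf
from matefit.model import conditional_pair_moments


def normalizer_by_quadrature(p, epsrel=1e-12):
    """Independent oracle: direct 2-D integration of fX fY exp(-a(x-y-d)^2)."""
    val, _ = integrate.dblquad(
        lambda y, x: (stats.norm.pdf(x, p.mu_x, p.sigma_x)
                      * stats.norm.pdf(y, p.mu_y, p.sigma_y)
                      * math.exp(-p.alpha * (x - y - p.delta) ** 2)),
        p.mu_x - 10 * p.sigma_x, p.mu_x + 10 * p.sigma_x,
        lambda x: p.mu_y - 10 * p.sigma_y, lambda x: p.mu_y + 10 * p.sigma_y,
        epsabs=1e-14, epsrel=epsrel)
    return val


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": -0.1}, {"sigma_x": 0.0}, {"sigma_y": -1.0},
        {"gamma": 0.0}, {"gamma": 1.5}, {"mu_x": float("nan")},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(alpha=0.5, delta=1.0, mu_x=10, mu_y=12,
                    sigma_x=2, sigma_y=2)
        base.update(kwargs)
        with pytest.raises(ValueError):
            mf.ModelParams(**base)

    def test_unit_scaling_rules(self, params):
        scaled = params.scaled(0.1)
        assert scaled.alpha == pytest.approx(params.alpha * 100)
        assert scaled.delta == pytest.approx(params.delta * 0.1)
        assert scaled.sigma_x == pytest.approx(params.sigma_x * 0.1)


class TestMatingProbability:
    @pytest.mark.parametrize("x, y, p, expected", [
        # at the optimum x - y = delta the exponent vanishes
        (13.0, 12.0, dict(alpha=2.3, delta=1.0, gamma=1.0), 1.0),
        # direct evaluation: exp(-0.5 * (3 - 1)^2)
        (12.0, 9.0, dict(alpha=0.5, delta=1.0, gamma=1.0),
         math.exp(-2.0)),
        # alpha = 0 is random mating at the ceiling
        (3.0, 17.0, dict(alpha=0.0, delta=0.0, gamma=0.7), 0.7),
    ])
    def test_known_values(self, x, y, p, expected):
        params = mf.ModelParams(mu_x=10, mu_y=12, sigma_x=2, sigma_y=2, **p)
        assert mf.mating_probability(x, y, params) == pytest.approx(
            expected, abs=1e-12)

    def test_nonfinite_trait_rejected(self, params):
        with pytest.raises(ValueError):
            mf.mating_probability(float("inf"), 1.0, params)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(x=st.floats(-50, 50), y=st.floats(-50, 50),
           alpha=st.floats(0, 10), delta=st.floats(-5, 5),
           gamma=st.floats(0.01, 1.0))
    def test_bounded_by_ceiling_and_maximised_at_offset(self, x, y, alpha,
                                                        delta, gamma):
        p = mf.ModelParams(alpha, delta, 10, 12, 2, 2, gamma)
        prob = mf.mating_probability(x, y, p)
        assert 0.0 <= prob <= gamma + 1e-15
        assert prob <= mf.mating_probability(y + delta, y, p) + 1e-15


class TestPairNormalizer:
    def test_random_mating_gives_one_exactly(self):
        p = mf.ModelParams(0.0, 3.0, 10, 12, 2, 2)
        assert mf.pair_normalizer(p) == 1.0

    def test_closed_form_value(self, params):
        # t = -4, lam = 9/8 => exp(-1/2) / 3
        assert mf.pair_normalizer(params) == pytest.approx(
            math.exp(-0.5) / 3.0, rel=1e-12)

    def test_centred_case_reduces_to_sqrt_term(self):
        # mu_x - mu_y - delta = 0: lam = 0, value = 1/sqrt(1 - 2t)
        p = mf.ModelParams(0.25, -2.0, 10, 12, 1, 1)
        assert mf.pair_normalizer(p) == pytest.approx(1 / math.sqrt(2),
                                                      rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 2.0])
    @pytest.mark.parametrize("delta", [-2.0, 1.0])
    @pytest.mark.parametrize("sigma", [0.5, 5.0])
    def test_matches_numerical_quadrature(self, alpha, delta, sigma):
        p = mf.ModelParams(alpha, delta, 10, 12, sigma, sigma)
        assert mf.pair_normalizer(p) == pytest.approx(
            normalizer_by_quadrature(p), rel=1e-8)

    def test_huge_alpha_stays_finite_in_log_space(self):
        p = mf.ModelParams(1e8, 5.0, 0, 50, 2, 2)
        lv = mf.log_pair_normalizer(p)
        assert np.isfinite(lv) and lv < 0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(alpha=st.floats(0, 50), delta=st.floats(-10, 10),
           sigma=st.floats(0.1, 10))
    def test_always_a_probability_ratio(self, alpha, delta, sigma):
        p = mf.ModelParams(alpha, delta, 10, 12, sigma, sigma)
        lv = mf.log_pair_normalizer(p)
        assert np.isfinite(lv) and lv <= 0.0
        # raw value may underflow to 0 at extreme mean/SD mismatch, but
        # never exceeds 1
        assert 0.0 <= mf.pair_normalizer(p) <= 1.0


class TestConditionalPairDensity:
    def test_random_mating_equals_product_of_marginals(self):
        p = mf.ModelParams(0.0, 0.0, 10, 12, 2, 3)
        x, y = 9.3, 14.1
        expected = (stats.norm.logpdf(x, 10, 2) + stats.norm.logpdf(y, 12, 3))
        assert mf.conditional_pair_logdensity(x, y, p) == pytest.approx(
            expected, abs=1e-12)

    def test_integrates_to_one(self, params):
        val, _ = integrate.dblquad(
            lambda y, x: math.exp(mf.conditional_pair_logdensity(x, y, params)),
            0, 20, lambda x: 2, lambda x: 22, epsabs=1e-10, epsrel=1e-10)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_equals_bivariate_normal_from_completing_the_square(self, params,
                                                                rng):
        mean, cov = conditional_pair_moments(params)
        mvn = stats.multivariate_normal(mean=mean, cov=cov)
        pts = rng.normal(size=(50, 2)) * 3 + mean
        ours = mf.conditional_pair_logdensity(pts[:, 0], pts[:, 1], params)
        np.testing.assert_allclose(ours, mvn.logpdf(pts), atol=1e-10)

    def test_moments_alpha_zero_recover_marginals(self):
        p = mf.ModelParams(0.0, 0.0, 10, 12, 2, 3)
        mean, cov = conditional_pair_moments(p)
        np.testing.assert_allclose(mean, [10, 12])
        np.testing.assert_allclose(cov, np.diag([4.0, 9.0]))


class TestLogLikelihood:
    def test_factorises_under_random_mating(self, sim_data):
        p = mf.ModelParams(0.0, 0.0, 10, 12, 2, 2)
        expected = (np.sum(stats.norm.logpdf(sim_data.all_x(), 10, 2))
                    + np.sum(stats.norm.logpdf(sim_data.all_y(), 12, 2)))
        assert mf.log_likelihood(p, sim_data) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_single_pair_assembles_from_verified_pieces(self, params):
        data = mf.TraitData.from_pairs([(10.0, 9.0)])
        expected = (stats.norm.logpdf(10, 10, 2) + stats.norm.logpdf(9, 12, 2)
                    - 0.5 * (10 - 9 - 1) ** 2
                    - math.log(math.exp(-0.5) / 3.0))
        assert mf.log_likelihood(params, data) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_duplicating_observations_doubles_loglik(self, params):
        d1 = mf.TraitData.from_pairs([(10, 9), (11, 12)], [8.5], [13.0])
        d2 = mf.TraitData.from_pairs([(10, 9), (11, 12)] * 2,
                                     [8.5] * 2, [13.0] * 2)
        assert mf.log_likelihood(params, d2) == pytest.approx(
            2 * mf.log_likelihood(params, d1), rel=1e-14)

    def test_empty_dataset_rejected(self, params):
        with pytest.raises(ValueError):
            mf.log_likelihood(params, mf.TraitData.from_pairs([]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(g1=st.floats(0.05, 1.0), g2=st.floats(0.05, 1.0))
    def test_invariant_to_gamma(self, sim_data, g1, g2):
        p1 = mf.ModelParams(0.5, 1, 10, 12, 2, 2, gamma=g1)
        p2 = mf.ModelParams(0.5, 1, 10, 12, 2, 2, gamma=g2)
        assert mf.log_likelihood(p1, sim_data) == mf.log_likelihood(p2,
                                                                    sim_data)

    def test_decreases_in_alpha_for_badly_matched_pairs(self):
        # all pairs far from the preferred offset: stronger preference can
        # only make the data less likely
        data = mf.TraitData.from_pairs([(10, 18), (9, 17), (11, 19)])
        lls = [mf.log_likelihood(mf.ModelParams(a, 0, 10, 12, 2, 2), data)
               for a in (0.0, 0.2, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_unit_change_shifts_loglik_by_jacobian(self, params, sim_data):
        c = 0.1
        n_obs = 2 * sim_data.n_pairs + sim_data.n_singles_x + sim_data.n_singles_y
        ll = mf.log_likelihood(params, sim_data)
        ll_scaled = mf.log_likelihood(params.scaled(c), sim_data.scaled(c))
        assert ll_scaled == pytest.approx(ll - n_obs * math.log(c), rel=1e-12)


class TestMultiPopulation:
    def test_single_population_reduces_to_loglik(self, params, sim_data):
        mp = mf.MultiPopData(populations=(("a", sim_data),))
        nuis = [(params.mu_x, params.mu_y, params.sigma_x, params.sigma_y)]
        assert mf.multipop_log_likelihood(0.5, 1.0, nuis, mp) == \
            pytest.approx(mf.log_likelihood(params, sim_data), rel=1e-14)

    def test_two_copies_double_the_loglik(self, params, sim_data):
        mp = mf.MultiPopData(populations=(("a", sim_data), ("b", sim_data)))
        nuis = [(10, 12, 2, 2)] * 2
        single = mf.log_likelihood(mf.ModelParams(0.5, 1, 10, 12, 2, 2),
                                   sim_data)
        assert mf.multipop_log_likelihood(0.5, 1.0, nuis, mp) == \
            pytest.approx(2 * single, rel=1e-14)

    def test_population_specific_means_profile_higher(self):
        rng = np.random.default_rng(7)
        base = mf.ModelParams(0.5, 1.0, 10, 12, 2, 2)
        shifted = mf.ModelParams(0.5, 1.0, 13, 15, 2, 2)
        d1 = mf.simulate_dataset(mf.SimulationConfig(params=base, n_pairs=80,
                                                     n_singles=80), rng)
        d2 = mf.simulate_dataset(mf.SimulationConfig(params=shifted,
                                                     n_pairs=80,
                                                     n_singles=80), rng)
        mp = mf.MultiPopData(populations=(("a", d1), ("b", d2)))
        grid = np.linspace(8, 17, 37)
        # free means: best (mu1, mu2) pair on the grid, keeping the observed
        # male-female mean gap; common mean: one grid value for both
        def ll(mu_a, mu_b):
            return mf.multipop_log_likelihood(
                0.5, 1.0, [(mu_a, mu_a + 2, 2, 2), (mu_b, mu_b + 2, 2, 2)], mp)
        best_free = max(ll(a, b) for a in grid for b in grid)
        best_common = max(ll(m, m) for m in grid)
        assert best_free >= best_common

    def test_nuisance_length_mismatch_rejected(self, sim_data):
        mp = mf.MultiPopData(populations=(("a", sim_data),))
        with pytest.raises(ValueError):
            mf.multipop_log_likelihood(0.5, 1.0, [(10, 12, 2, 2)] * 2, mp)

    def test_duplicate_labels_rejected(self, sim_data):
        with pytest.raises(ValueError):
            mf.MultiPopData(populations=(("a", sim_data), ("a", sim_data)))


class TestTraitData:
    def test_pair_lengths_must_match(self):
        with pytest.raises(ValueError):
            mf.TraitData(np.arange(3.0), np.arange(2.0))

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError):
            mf.TraitData(np.array([1.0, np.nan]), np.array([1.0, 2.0]))

    def test_counts_and_pooling(self, sim_data):
        assert sim_data.n_pairs == 300
        assert sim_data.n_singles_x == sim_data.n_singles_y == 150
        assert sim_data.all_x().size == 450
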