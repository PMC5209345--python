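"""Probability computations, invariants and free-parameter accounting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from mixirt.errors import DegenerateItemError, InvalidParameterError
from mixirt.model import (
    MISSING,
    ModelSpec,
    ParameterSet,
    QuadratureGrid,
    ResponseMatrix,
    category_probabilities,
    class_conditional_pattern_probability,
    count_free_parameters,
    log_likelihood,
    marginal_pattern_probability,
)
from mixirt.published import FIGURE_DISCRIMINATIONS, ORDERED_THRESHOLDS


class TestCategoryProbabilities:
    def test_all_zero_thresholds_uniform(self):
        p = category_probabilities(0.0, np.zeros(10), 1.0)
        assert np.allclose(p, 1.0 / 11, atol=1e-12)

    def test_two_category_logistic_closed_form(self):
        p = category_probabilities(2.0, [0.0], 1.0)
        assert p[1] == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-12)

    def test_adjacent_curves_intersect_at_thresholds(self):
        """CCCs of categories x-1 and x cross exactly at tau_x, any slope."""
        for delta in FIGURE_DISCRIMINATIONS:
            for s, tau_s in enumerate(ORDERED_THRESHOLDS, start=1):
                p = category_probabilities(tau_s, ORDERED_THRESHOLDS, delta)
                assert p[s - 1] == pytest.approx(p[s], abs=1e-10)

    def test_extreme_category_monotonicity(self):
        theta = np.linspace(-5, 5, 101)
        p = category_probabilities(theta, ORDERED_THRESHOLDS, 1.5)
        assert np.all(np.diff(p[:, 0]) < 0)
        assert np.all(np.diff(p[:, -1]) > 0)

    def test_higher_slope_sharpens_interior_peaks(self):
        theta = np.linspace(-6, 6, 2401)
        p_lo = category_probabilities(theta, ORDERED_THRESHOLDS, 1.5)
        p_hi = category_probabilities(theta, ORDERED_THRESHOLDS, 3.0)
        for cat in range(1, 10):
            assert p_hi[:, cat].max() > p_lo[:, cat].max()

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            category_probabilities(0.0, [0.0], -1.0)
        with pytest.raises(DegenerateItemError):
            category_probabilities(0.0, [], 1.0)

    @given(
        theta=st.floats(-30, 30),
        delta=st.floats(0.05, 10),
        tau=st.lists(st.floats(-8, 8), min_size=1, max_size=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_property(self, theta, delta, tau):
        p = category_probabilities(theta, np.array(tau), delta)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestPatternProbabilities:
    def test_single_item_pattern_reduces_to_item_probability(self, small_mixture):
        single = ParameterSet(
            thresholds=small_mixture.thresholds[:, :1],
            discriminations=small_mixture.discriminations[:, :1],
            mixing=small_mixture.mixing,
            variances=small_mixture.variances,
            category_counts=small_mixture.category_counts[:1],
        )
        p_item = category_probabilities(0.3, single.thresholds[0, 0], 1.0)
        for x in range(3):
            got = class_conditional_pattern_probability([x], 0, single, 0.3)
            assert got == pytest.approx(p_item[x], abs=1e-14)

    def test_all_missing_pattern_is_unit_probability(self, small_mixture):
        got = class_conditional_pattern_probability(
            [MISSING, MISSING], 0, small_mixture, 0.0
        )
        assert got == 1.0

    def test_conditional_patterns_sum_to_one(self, small_mixture):
        for theta in (-1.3, 0.0, 2.1):
            total = sum(
                class_conditional_pattern_probability([a, b], 1, small_mixture, theta)
                for a, b in itertools.product(range(3), range(3))
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_marginal_patterns_sum_to_one(self, small_mixture, grid21):
        total = sum(
            marginal_pattern_probability([a, b], small_mixture, grid21)
            for a, b in itertools.product(range(3), range(3))
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_mixture_collapse_with_identical_classes(self, grid21):
        tau = np.array([[[-0.5, 0.8]]])
        one = ParameterSet(tau, np.ones((1, 1)), np.ones(1), np.ones(1), np.array([3]))
        for pi in ([0.5, 0.5], [0.9, 0.1]):
            two = ParameterSet(
                np.repeat(tau, 2, axis=0),
                np.ones((2, 1)),
                np.array(pi),
                np.ones(2),
                np.array([3]),
            )
            for x in range(3):
                assert marginal_pattern_probability(
                    [x], two, grid21
                ) == pytest.approx(marginal_pattern_probability([x], one, grid21), abs=1e-12)

    def test_quadrature_node_doubling(self, small_mixture):
        g1 = QuadratureGrid.gauss_hermite(21)
        g2 = QuadratureGrid.gauss_hermite(42)
        for pattern in ([0, 2], [1, 1], [2, 0]):
            a = marginal_pattern_probability(pattern, small_mixture, g1)
            b = marginal_pattern_probability(pattern, small_mixture, g2)
            assert abs(a - b) < 1e-6


class TestLogLikelihood:
    def test_additive_over_identical_persons(self, small_mixture, grid21):
        one = ResponseMatrix(np.array([[1, 2]]), ["a", "b"], [3, 3])
        five = ResponseMatrix(np.tile([1, 2], (5, 1)), ["a", "b"], [3, 3])
        assert log_likelihood(five, small_mixture, grid21) == pytest.approx(
            5 * log_likelihood(one, small_mixture, grid21), abs=1e-10
        )

    def test_matches_dense_integration_oracle(self, small_mixture, grid21):
        """Tiny case vs an independent midpoint-rule integration."""
        data = ResponseMatrix(
            np.array([[0, 1], [2, 2], [1, 0]]), ["a", "b"], [3, 3]
        )
        theta = np.linspace(-9, 9, 10001)
        dt = theta[1] - theta[0]
        oracle = 0.0
        for row in data.values:
            marg = 0.0
            for g in range(2):
                dens = norm.pdf(theta, scale=np.sqrt(small_mixture.variances[g]))
                like = np.ones_like(theta)
                for i, x in enumerate(row):
                    pi_ = category_probabilities(
                        theta,
                        small_mixture.thresholds[g, i],
                        small_mixture.discriminations[g, i],
                    )
                    like *= pi_[:, x]
                marg += small_mixture.mixing[g] * np.sum(like * dens) * dt
            oracle += np.log(marg)
        assert log_likelihood(data, small_mixture, grid21) == pytest.approx(
            oracle, abs=1e-6
        )


class TestVariantEquivalences:
    """Tied-parameter variants must collapse onto their restricted forms."""

    def _ll(self, data, params, grid):
        return log_likelihood(data, params, grid)

    def test_nested_collapses(self, grid21):
        rng = np.random.default_rng(5)
        tau = rng.normal(size=(1, 3, 2))
        data = ResponseMatrix(
            rng.integers(0, 3, size=(40, 3)), ["a", "b", "c"], [3, 3, 3]
        )
        # GPCM with all slopes 1 == PCM
        gpcm = ParameterSet(tau, np.ones((1, 3)), np.ones(1), np.ones(1), [3, 3, 3])
        pcm = ParameterSet(tau, np.ones((1, 3)), np.ones(1), np.ones(1), [3, 3, 3])
        assert self._ll(data, gpcm, grid21) == pytest.approx(
            self._ll(data, pcm, grid21), abs=1e-10
        )
        # mGPCM with class-tied parameters == GPCM (G = 1 equivalent)
        disc = np.array([[1.0, 0.7, 1.4]])
        g1 = ParameterSet(tau, disc, np.ones(1), np.ones(1), [3, 3, 3])
        g2 = ParameterSet(
            np.repeat(tau, 2, axis=0),
            np.repeat(disc, 2, axis=0),
            np.array([0.3, 0.7]),
            np.ones(2),
            [3, 3, 3],
        )
        assert self._ll(data, g2, grid21) == pytest.approx(
            self._ll(data, g1, grid21), abs=1e-10
        )


class TestFreeParameterCounts:
    @pytest.mark.parametrize(
        "variant,G,expected",
        [
            ("rmgpcm", 3, 159),
            ("rmgpcm", 1, 55),
            ("gpcm", 1, 55),
            ("mgpcm", 3, 169),
            ("mpcm", 3, 155),
            ("rmgpcm", 2, 107),
            ("rmgpcm", 4, 211),
            ("rmgpcm", 5, 263),
        ],
    )
    def test_published_accounting(self, variant, G, expected):
        spec = ModelSpec(variant, G, np.full(5, 11))
        assert count_free_parameters(spec) == expected

    def test_ragged_items(self):
        spec = ModelSpec("rmgpcm", 2, [4, 3, 5])
        # thresholds 2*(3+2+4)=18, variances 2, mixing 1, slopes 2
        assert count_free_parameters(spec) == 23


class TestResponseMatrixValidation:
    def test_out_of_range_category_rejected(self):
        with pytest.raises(Exception, match="out of range"):
            ResponseMatrix(np.array([[0, 11]]), ["a", "b"], [11, 11])

    def test_all_missing_person_rejected(self):
        with pytest.raises(Exception, match="no observed"):
            ResponseMatrix(
                np.array([[0, 1], [MISSING, MISSING]]), ["a", "b"], [3, 3]
            )
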