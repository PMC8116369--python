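"""Graded-response-model machinery: probabilities, EAP, conversion tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promisgh.grm import (
    ItemParameters,
    QuadratureGrid,
    ScoringError,
    category_probabilities,
    category_probability,
    default_grid,
    eap_pattern_score,
    score_population,
    summed_score_likelihoods,
    summed_score_table,
    to_tscore,
)

from conftest import dense_eap


@st.composite
def grm_items(draw):
    a = draw(st.floats(0.5, 4.0))
    n_thresh = draw(st.integers(1, 4))
    raw = draw(
        st.lists(
            st.floats(-3.0, 3.0), min_size=n_thresh, max_size=n_thresh, unique=True
        )
    )
    b = tuple(sorted(raw))
    if any(y - x < 1e-3 for x, y in zip(b, b[1:])):
        b = tuple(x + 0.01 * i for i, x in enumerate(b))
    return ItemParameters(item_id="Global01", a=a, b=b)


class TestCategoryProbability:
    def test_normalization_on_every_grid_node(self, params):
        grid = default_grid()
        for item in params.values():
            probs = category_probabilities(item, grid.nodes)
            assert np.all(probs >= 0)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_thresholds_give_symmetric_extremes(self):
        item = ItemParameters("Global01", a=2.0, b=(-1.5, -0.5, 0.5, 1.5))
        assert category_probability(0.0, item, 1) == pytest.approx(
            category_probability(0.0, item, 5), abs=1e-12
        )

    def test_frozen_regression_value(self):
        # direct evaluation of the two logistic terms:
        # 1/(1+e^{-1.5(0.5+1)}) - 1/(1+e^{-1.5*0.5})
        item = ItemParameters("Global01", a=1.5, b=(-2.0, -1.0, 0.0, 1.0))
        assert category_probability(0.5, item, 3) == pytest.approx(
            0.22547183592549758, abs=1e-12
        )

    def test_invalid_category_rejected(self):
        item = ItemParameters("Global01", a=1.5, b=(-1.0, 1.0))
        with pytest.raises(ScoringError, match="category"):
            category_probability(0.0, item, 4)

    @given(item=grm_items(), theta=st.floats(-4.0, 4.0))
    def test_probabilities_form_a_distribution(self, item, theta):
        probs = category_probabilities(item, theta)[0]
        assert np.all(probs >= -1e-15)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestPatternEAP:
    def test_all_missing_returns_prior(self, gph_items):
        r = eap_pattern_score([None] * 4, gph_items)
        assert r.all_missing
        assert r.theta_hat == pytest.approx(0.0, abs=1e-3)
        assert r.se_theta == pytest.approx(1.0, abs=1e-3)
        assert r.t_score == pytest.approx(50.0, abs=1e-2)

    @pytest.mark.parametrize(
        "pattern",
        [
            (3, 4, 2, 5),
            (1, 1, 1, 1),
            (5, 5, 5, 5),
            (None, 3, None, 2),
            (4, None, None, None),
        ],
    )
    def test_matches_dense_integration_oracle(self, gph_items, pattern):
        oracle_theta, oracle_se = dense_eap(pattern, gph_items)
        r = eap_pattern_score(list(pattern), gph_items)
        assert r.theta_hat == pytest.approx(oracle_theta, abs=1e-6)
        assert r.se_theta == pytest.approx(oracle_se, abs=1e-6)

    def test_extreme_patterns_ordered(self, gph_items):
        lo = eap_pattern_score([1, 1, 1, 1], gph_items).theta_hat
        hi = eap_pattern_score([5, 5, 5, 5], gph_items).theta_hat
        assert hi > lo

    def test_length_mismatch_rejected(self, gph_items):
        with pytest.raises(ScoringError, match="responses"):
            eap_pattern_score([1, 2], gph_items)

    def test_category_out_of_range_rejected(self, gph_items):
        with pytest.raises(ScoringError, match="outside"):
            eap_pattern_score([6, 1, 1, 1], gph_items)

    def test_shrinkage_bounds(self, gph_items):
        grid = default_grid()
        for pattern in [(1, 1, 1, 1), (5, 5, 5, 5), (2, None, None, None)]:
            r = eap_pattern_score(list(pattern), gph_items, grid)
            assert abs(r.theta_hat) < np.abs(grid.nodes).max()
            assert r.se_theta <= 1.0 + 1e-3

    def test_vectorized_scoring_equals_scalar(self, gph_items):
        patterns = [
            (3, 4, 2, 5),
            (1, 1, 1, 1),
            (0, 3, 0, 2),  # 0 = missing in matrix form
            (5, 5, 5, 5),
        ]
        matrix = np.array(patterns)
        theta, se, n_items = score_population(matrix, gph_items)
        for i, pat in enumerate(patterns):
            scalar = eap_pattern_score(
                [None if c == 0 else c for c in pat], gph_items
            )
            assert theta[i] == pytest.approx(scalar.theta_hat, abs=1e-12)
            assert se[i] == pytest.approx(scalar.se_theta, abs=1e-12)
            assert n_items[i] == scalar.n_items_used


class TestSummedScoreTable:
    def test_single_item_base_case(self, params):
        item = params["Global03"]
        grid = default_grid()
        sums, L = summed_score_likelihoods([item], grid.nodes)
        assert list(sums) == [1, 2, 3, 4, 5]
        np.testing.assert_allclose(
            L, category_probabilities(item, grid.nodes).T, atol=1e-14
        )

    def test_two_item_recursion_matches_enumeration(self, params):
        items = [params["Global03"], params["Global06"]]
        nodes = np.linspace(-3, 3, 21)
        sums, L = summed_score_likelihoods(items, nodes)
        probs = [category_probabilities(it, nodes) for it in items]
        for s_idx, s in enumerate(sums):
            brute = np.zeros_like(nodes)
            for k1, k2 in itertools.product(range(1, 6), repeat=2):
                if k1 + k2 == s:
                    brute += probs[0][:, k1 - 1] * probs[1][:, k2 - 1]
            np.testing.assert_allclose(L[s_idx], brute, atol=1e-12)

    def test_table_shape_and_monotonicity(self, gph_items):
        table = summed_score_table(gph_items, subscale_id="GPH")
        assert list(table.sums) == list(range(4, 21))
        assert np.all(np.diff(table.t_scores) >= 0)
        assert np.all(table.se_t > 0)

    def test_lookup(self, gph_items):
        table = summed_score_table(gph_items)
        t, se = table.lookup(4)
        assert t == pytest.approx(float(table.t_scores[0]))
        with pytest.raises(ScoringError, match="unattainable"):
            table.lookup(3)

    def test_empty_item_list_rejected(self):
        with pytest.raises(ScoringError, match="at least one"):
            summed_score_table([])

    def test_sum_score_eap_is_mixture_of_pattern_eaps(self, gph_items):
        # the sum-score estimator pools patterns by model probability: the
        # T for sum s must equal the probability-weighted average of the
        # pattern EAPs of every pattern with that sum
        grid = default_grid()
        table = summed_score_table(gph_items, grid)
        num = {int(s): 0.0 for s in table.sums}
        den = {int(s): 0.0 for s in table.sums}
        for pat in itertools.product(range(1, 6), repeat=4):
            like = np.ones_like(grid.nodes)
            for item, k in zip(gph_items, pat):
                like *= category_probabilities(item, grid.nodes)[:, k - 1]
            marginal = float(grid.weights @ like)
            r = eap_pattern_score(list(pat), gph_items, grid)
            num[sum(pat)] += marginal * r.theta_hat
            den[sum(pat)] += marginal
        for s, t in zip(table.sums, table.t_scores):
            mixture_t = 50.0 + 10.0 * num[int(s)] / den[int(s)]
            assert t == pytest.approx(mixture_t, abs=1e-9)


class TestTMetric:
    @pytest.mark.parametrize(
        "theta,expected", [(0.0, 50.0), (-0.53, 44.7), (1.0, 60.0)]
    )
    def test_linear_map(self, theta, expected):
        assert to_tscore(theta) == pytest.approx(expected)

    def test_grid_validation(self):
        with pytest.raises(ScoringError):
            QuadratureGrid(nodes=np.array([0.0, 0.0]), weights=np.array([1.0, 1.0]))
        with pytest.raises(ScoringError):
            QuadratureGrid(nodes=np.array([0.0, 1.0]), weights=np.array([1.0, -1.0]))

    def test_prior_weights_normalized(self):
        grid = default_grid()
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(grid.nodes) > 0)
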