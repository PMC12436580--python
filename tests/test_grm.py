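"""Graded-response-model kernels: probabilities, information, likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epdscat import ItemBank, item_information, item_response_probs, response_loglik
from epdscat.grm import category_prob_table, information_trace_profile

from conftest import toy_item_bank


def direct_logistic_categories(a, b, theta):
    """Independent hand evaluation of the GRM category probabilities."""
    pstar = [1.0] + [1.0 / (1.0 + math.exp(-a * (theta - bk))) for bk in b] + [0.0]
    return np.array([pstar[k] - pstar[k + 1] for k in range(len(b) + 1)])


class TestItemResponseProbs:
    def test_midpoint_cumulative_is_half(self):
        bank = toy_item_bank(a=1.0, b=(0.0,))
        cum, cat = item_response_probs(bank, 0, [0.0])
        assert cum[0] == pytest.approx(0.5)
        assert cat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_probs_independent_of_theta(self):
        bank = ItemBank(np.zeros((1, 1)), np.array([[1.0, 0.0, -1.0]]), [0], si_item=0)
        _, cat_a = item_response_probs(bank, 0, [-3.0])
        _, cat_b = item_response_probs(bank, 0, [4.0])
        np.testing.assert_allclose(cat_a, cat_b, atol=1e-14)

    def test_matches_hand_evaluated_logistic(self):
        a, b, theta = 1.5, (-1.0, 0.0, 1.0), 0.5
        bank = toy_item_bank(a=a, b=b)
        _, cat = item_response_probs(bank, 0, [theta])
        np.testing.assert_allclose(cat, direct_logistic_categories(a, b, theta), atol=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.floats(0.1, 4.0),
        b1=st.floats(-2.0, 1.0),
        g=st.floats(0.1, 2.0),
        theta=st.floats(-5.0, 5.0),
    )
    def test_simplex_and_decreasing_cumulative(self, a, b1, g, theta):
        bank = toy_item_bank(a=a, b=(b1, b1 + g, b1 + 2 * g))
        cum, cat = item_response_probs(bank, 0, [theta])
        assert np.all(np.diff(cum) < 0)
        assert np.all(cat >= 0)
        assert cat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cumulative_monotone_in_theta(self):
        bank = toy_item_bank()
        thetas = np.linspace(-4, 4, 41)[:, None]
        cum = np.array([item_response_probs(bank, 0, t)[0] for t in thetas])
        assert np.all(np.diff(cum, axis=0) > 0)

    def test_dimension_mismatch_raises(self):
        bank = toy_item_bank()
        with pytest.raises(ValueError, match="dimension"):
            item_response_probs(bank, 0, [0.0, 0.0])

    def test_unordered_intercepts_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            ItemBank(np.ones((1, 1)), np.array([[0.0, 1.0, -1.0]]), [0], si_item=0)


def numeric_information(bank, item, theta, h=1e-4):
    """Central-difference oracle: I = -sum_k P_k d^2 log P_k / d theta^2."""

    def logp(t):
        _, cat = item_response_probs(bank, item, [t])
        return np.log(cat)

    _, cat = item_response_probs(bank, item, [theta])
    second = (logp(theta + h) - 2 * logp(theta) + logp(theta - h)) / h**2
    return -(cat * second).sum()


class TestItemInformation:
    def test_dichotomous_closed_form(self):
        a, b = 1.7, 0.4
        bank = ItemBank.from_thresholds(np.array([a]), np.array([[b]]), dimension=1, si_item=0)
        for theta in (-1.0, b, 2.0):
            cum, _ = item_response_probs(bank, 0, [theta])
            expected = a**2 * cum[0] * (1 - cum[0])
            assert item_information(bank, 0, [theta])[0, 0] == pytest.approx(expected, rel=1e-12)
        assert item_information(bank, 0, [b])[0, 0] == pytest.approx(a**2 / 4)

    def test_zero_slope_gives_zero_matrix(self):
        bank = ItemBank(np.zeros((1, 1)), np.array([[1.0, 0.0, -1.0]]), [0], si_item=0)
        assert np.all(item_information(bank, 0, [1.3]) == 0)

    @pytest.mark.parametrize("theta", [-2.0, -0.3, 0.5, 1.8])
    def test_matches_numeric_second_derivative(self, theta):
        bank = toy_item_bank(a=2.1, b=(-0.8, 0.3, 1.5))
        got = item_information(bank, 0, [theta])[0, 0]
        assert got == pytest.approx(numeric_information(bank, 0, theta), abs=1e-6)

    def test_simple_structure_rank_one(self):
        slopes = np.zeros((1, 3))
        slopes[0, 1] = 2.0
        bank = ItemBank(slopes, np.array([[1.0, -1.0, -3.0]]), [1], si_item=0)
        info = item_information(bank, 0, [0.2, -0.5, 1.0])
        assert info.shape == (3, 3)
        assert np.linalg.matrix_rank(info, tol=1e-12) == 1
        assert info[0, 0] == 0 and info[2, 2] == 0 and info[1, 1] > 0
        assert np.all(np.linalg.eigvalsh(info) >= -1e-12)

    def test_trace_profile_consistent_with_matrices(self, bank1):
        thetas = np.array([[-1.0], [0.0], [2.0]])
        prof = information_trace_profile(bank1, thetas)
        for j, t in enumerate(thetas):
            for i in range(bank1.n_items):
                assert prof[j, i] == pytest.approx(np.trace(item_information(bank1, i, t)), rel=1e-12)


class TestResponseLoglik:
    def test_empty_pattern_is_zero(self, bank1):
        assert response_loglik(bank1, [-1] * 10, [0.0]) == 0.0

    def test_single_dichotomous_item_log_half(self):
        bank = ItemBank.from_thresholds(np.array([1.0]), np.array([[0.0]]), dimension=1, si_item=0)
        assert response_loglik(bank, [1], [0.0]) == pytest.approx(math.log(0.5))

    def test_compositional_sum_over_items(self, bank1):
        rng = np.random.default_rng(3)
        pattern = rng.integers(0, 4, size=10)
        theta = [0.7]
        expected = sum(
            math.log(item_response_probs(bank1, i, theta)[1][pattern[i]]) for i in range(10)
        )
        assert response_loglik(bank1, pattern, theta) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_response_names_item(self, bank1):
        pattern = [0] * 10
        pattern[4] = 7
        with pytest.raises(ValueError, match="item index 4"):
            response_loglik(bank1, pattern, [0.0])

    def test_category_table_matches_per_item(self, bank1):
        thetas = np.array([[-0.4], [1.2]])
        table = category_prob_table(bank1, thetas)
        for j, t in enumerate(thetas):
            for i in range(10):
                np.testing.assert_allclose(
                    table[j, i], item_response_probs(bank1, i, t)[1], atol=1e-14
                )


class TestSerialization:
    def test_csv_round_trip_bit_exact(self, bank1, tmp_path):
        path = tmp_path / "bank.csv"
        bank1.to_csv(path)
        back = ItemBank.from_csv(path)
        assert np.array_equal(back.slopes, bank1.slopes)
        assert np.array_equal(back.intercepts, bank1.intercepts)
        assert np.array_equal(back.factor_index, bank1.factor_index)

    def test_json_round_trip_bit_exact(self, bank1, tmp_path):
        path = tmp_path / "bank.json"
        bank1.to_json(path)
        back = ItemBank.from_json(path)
        assert np.array_equal(back.slopes, bank1.slopes)
        assert np.array_equal(back.intercepts, bank1.intercepts)
        assert back.si_item == bank1.si_item
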