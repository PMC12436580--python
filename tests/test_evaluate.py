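"""Classification, predictive values, fairness audit, reliability, agreement."""

import numpy as np
import pytest

from epdscat import (
    classify_cat_result,
    classify_full_test,
    cronbach_alpha,
    diagnostic_metrics,
    fnr_parity,
    score_agreement,
)


class TestFullTestClassification:
    @pytest.mark.parametrize(
        "total,si,tier",
        [
            (13, 0, "high"),
            (30, 0, "high"),
            (8, 0, "moderate"),
            (12, 0, "moderate"),
            (7, 0, "low"),
            (5, 0, "low"),
            (5, 2, "high"),  # suicidal-ideation override
            (0, 1, "high"),
        ],
    )
    def test_tiers(self, total, si, tier):
        c = classify_full_test(total, si)
        assert c.tier == tier
        assert c.positive == (tier != "low")

    def test_out_of_range_total_rejected(self):
        with pytest.raises(ValueError):
            classify_full_test(31, 0)
        with pytest.raises(ValueError):
            classify_full_test(-1, 0)


class TestCatClassification:
    def test_cutoff_inclusive(self):
        assert classify_cat_result(8.0, 0).positive

    def test_si_override_below_cutoff(self):
        assert classify_cat_result(7.99, 1).positive

    def test_below_cutoff_negative(self):
        assert not classify_cat_result(7.99, 0).positive


class TestDiagnosticMetrics:
    def test_perfect_agreement(self):
        truth = np.array([True, False, True, False])
        m = diagnostic_metrics(truth, truth)
        assert m.npv == 1.0 and m.ppv == 1.0 and m.fnr == 0.0

    def test_npv_arithmetic(self):
        truth = np.concatenate([np.zeros(988, bool), np.ones(12, bool)])
        predicted = np.zeros(1000, bool)
        m = diagnostic_metrics(truth, predicted)
        assert m.tn == 988 and m.fn == 12
        assert m.npv == pytest.approx(0.988)
        assert m.ppv is None  # no positive predictions

    def test_exhaustive_small_tables(self):
        """Counts and ratios match the brute-force definition on all
        paired boolean vectors of length 4."""
        from itertools import product

        for truth in product([0, 1], repeat=4):
            for pred in product([0, 1], repeat=4):
                m = diagnostic_metrics(np.array(truth, bool), np.array(pred, bool))
                tp = sum(t and p for t, p in zip(truth, pred))
                fn = sum(t and not p for t, p in zip(truth, pred))
                tn = sum(not t and not p for t, p in zip(truth, pred))
                fp = sum(not t and p for t, p in zip(truth, pred))
                assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
                if tn + fn:
                    assert m.npv == pytest.approx(tn / (tn + fn))
                if fn + tp:
                    assert m.fnr == pytest.approx(fn / (fn + tp))


def _mk(truth_pos, pred_neg_among_pos, group, n_neg=0):
    """Build truth/pred/group vectors: truth_pos positives of which
    pred_neg_among_pos are missed, plus n_neg true negatives."""
    truth = [True] * truth_pos + [False] * n_neg
    pred = [False] * pred_neg_among_pos + [True] * (truth_pos - pred_neg_among_pos)
    pred += [False] * n_neg
    groups = [group] * (truth_pos + n_neg)
    return truth, pred, groups


class TestFNRParity:
    def test_identical_groups_give_zero_chisquare(self):
        t1, p1, g1 = _mk(50, 5, "A")
        t2, p2, g2 = _mk(50, 5, "B")
        rep = fnr_parity(t1 + t2, p1 + p2, g1 + g2, "A")
        assert rep.chi2 == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(1.0) for v in rep.parity_ratio.values())

    def test_hand_computed_pearson_statistic(self):
        # groups: FN/TP = 5/45 and 10/40; expected FN = 7.5 each;
        # chi2 = 2*(2.5^2/7.5) + 2*(2.5^2/42.5) = 1.960784...
        t1, p1, g1 = _mk(50, 5, "A")
        t2, p2, g2 = _mk(50, 10, "B")
        rep = fnr_parity(t1 + t2, p1 + p2, g1 + g2, "A")
        assert rep.chi2 == pytest.approx(2 * 6.25 / 7.5 + 2 * 6.25 / 42.5, rel=1e-12)
        assert rep.df == 1
        assert rep.fnr["A"] == pytest.approx(0.1)
        assert rep.fnr["B"] == pytest.approx(0.2)
        assert rep.parity_ratio["B"] == pytest.approx(2.0)
        assert rep.overall_fnr == pytest.approx(15 / 100)

    def test_zero_positive_group_dropped_with_df_reduction(self):
        t1, p1, g1 = _mk(40, 4, "A")
        t2, p2, g2 = _mk(40, 6, "B")
        truth = t1 + t2 + [False] * 20
        pred = p1 + p2 + [False] * 20
        groups = g1 + g2 + ["C"] * 20
        with pytest.warns(UserWarning, match="no full-test positives"):
            rep = fnr_parity(truth, pred, groups, "A")
        assert rep.dropped_groups == ["C"]
        assert rep.df == 1

    def test_missing_reference_group_raises(self):
        t, p, g = _mk(50, 5, "A")
        with pytest.raises(ValueError, match="reference"):
            fnr_parity(t, p, g, "Z")


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        col = np.random.default_rng(0).integers(0, 4, size=100)
        X = np.tile(col[:, None], (1, 5))
        alpha, _ = cronbach_alpha(X)
        assert alpha == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 4, size=(5000, 2))
        alpha, _ = cronbach_alpha(X)
        assert abs(alpha) < 0.1

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        base = rng.standard_normal((200, 1))
        X = np.clip(np.round(base + rng.standard_normal((200, 6))), 0, 3)
        alpha, ci = cronbach_alpha(X)
        ref_alpha, ref_ci = pg.cronbach_alpha(pd.DataFrame(X))
        assert alpha == pytest.approx(ref_alpha, abs=1e-10)
        assert ci[0] == pytest.approx(ref_ci[0], abs=0.01)
        assert ci[1] == pytest.approx(ref_ci[1], abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))


class TestScoreAgreement:
    def test_identity_and_negation(self):
        x = np.arange(10.0)
        r, _, _ = score_agreement(x, x)
        assert r == pytest.approx(1.0)
        r, _, _ = score_agreement(-x, x)
        assert r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            score_agreement(np.ones(5), np.arange(5.0))
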