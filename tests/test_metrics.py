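"""Confusion-matrix metrics, QWK oracle equivalence, ROC/AUC, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pneumostage import metrics
from pneumostage.metrics import (basic_metrics, confusion, load_fixture_confusion,
                                 qwk, roc_auc, stability_analysis)


def brute_force_qwk(cm):
    """Independent double-summation implementation of the kappa formula."""
    cm = np.asarray(cm, float)
    k = cm.shape[0]
    n = cm.sum()
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2 / (k - 1) ** 2
            e = cm[i, :].sum() * cm[:, j].sum() / n
            num += w * cm[i, j]
            den += w * e
    return 1.0 - num / den


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion([0, 1, 2, 3], [0, 1, 2, 3])
        assert np.array_equal(cm, np.eye(4, dtype=int))

    def test_swapped_pair_anti_diagonal(self):
        cm = confusion([0, 1], [1, 0])
        assert cm[0, 1] == 1 and cm[1, 0] == 1 and cm.sum() == 2

    def test_fixture_row_margins_match_test_set_composition(self):
        cm = load_fixture_confusion("singlemodel")
        assert cm.sum(axis=1).tolist() == [47, 30, 15, 8]
        assert cm.sum() == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestBasicMetrics:
    def test_identity_matrix_perfect_scores(self):
        rep = basic_metrics(np.diag([5, 3, 2, 1]))
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.f1.values())

    def test_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 20, (4, 4))
        rep = basic_metrics(cm)
        micro = sum(cm[i, i] for i in range(4)) / cm.sum()
        assert rep.accuracy == pytest.approx(micro)

    def test_undefined_ratio_reported_as_zero_with_flag(self):
        cm = np.array([[3, 0], [1, 0]])  # class 1 never predicted
        rep = basic_metrics(cm, class_names=("a", "b"))
        assert rep.precision["b"] == 0.0
        assert "precision_b" in rep.undefined


class TestQwk:
    def test_diagonal_matrix_is_one(self):
        assert qwk(np.diag([4, 1, 7, 2])) == pytest.approx(1.0)

    def test_independence_outer_product_is_zero(self):
        rows = np.array([10, 20, 5, 15], float)
        cols = np.array([12, 18, 8, 12], float)
        cm = np.outer(rows, cols) / 50
        assert qwk(cm) == pytest.approx(0.0, abs=1e-12)

    def test_transpose_invariance_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            cm = rng.integers(0, 30, (4, 4)) + np.eye(4, dtype=int)
            assert qwk(cm) == pytest.approx(qwk(cm.T), abs=1e-12)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            cm = rng.integers(0, 50, (4, 4)) + np.eye(4, dtype=int)
            assert abs(qwk(cm) - brute_force_qwk(cm)) < 1e-12

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            qwk(np.array([[5, 0], [0, 0]]))

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 40, (4, 4)) + np.eye(4, dtype=int)
        assert qwk(cm) <= 1.0 + 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_pairwise_enumeration_example(self):
        # pairs: 3 concordant of 4 -> 0.75
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_equals_mann_whitney_on_random_scores(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(30), 2)  # rounding creates ties
            _, auc = roc_auc(y, s)
            pos, neg = s[y == 1], s[y == 0]
            gt = (pos[:, None] > neg[None, :]).sum()
            tie = (pos[:, None] == neg[None, :]).sum()
            mw = (gt + 0.5 * tie) / (len(pos) * len(neg))
            assert auc == pytest.approx(mw, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestStability:
    @staticmethod
    def _threshold_model(img):
        return int(img.mean() > 0.35)

    def test_identity_perturbation_is_one(self):
        imgs = [np.random.default_rng(i).random((16, 16)).astype(np.float32) for i in range(5)]
        out = stability_analysis(self._threshold_model, imgs, [0], [0.0])
        assert out[0, 0] == 1.0

    def test_single_image_consistency_binary(self):
        img = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        out = stability_analysis(self._threshold_model, [img], [0, 2], [0.0, 0.3], seed=1)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_consistency_decreases_with_perturbation(self):
        rng = np.random.default_rng(4)
        imgs = [(rng.random((16, 16)) * 0.7).astype(np.float32) for _ in range(40)]
        out = stability_analysis(self._threshold_model, imgs, [0, 1], [0.0, 0.5], seed=2)
        assert out[-1, -1] <= out[0, 0]


class TestFixtureDiscrepancies:
    def test_multistage_printed_cells_do_not_recompute(self):
        """Two printed cells disagree with their own confusion matrix; we
        assert the recomputed values and the fact of the disagreement."""
        cm = load_fixture_confusion("multistage")
        recomputed_qwk = qwk(cm)
        printed_qwk, expected_recomputed = metrics.EXPECTED_DISCREPANCIES[("multistage", "qwk")]
        assert round(recomputed_qwk, 2) != printed_qwk
        assert recomputed_qwk == pytest.approx(expected_recomputed, abs=5e-4)
        rep = basic_metrics(cm)
        printed_p, recomputed_p = metrics.EXPECTED_DISCREPANCIES[("multistage", "precision_StageI")]
        assert round(rep.precision["StageI"], 2) != printed_p
        assert rep.precision["StageI"] == pytest.approx(recomputed_p, abs=1e-9)
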