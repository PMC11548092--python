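"""Confusion/metric/ROC correctness against brute-force and rank-statistic
oracles."""
import numpy as np
import pytest

from semgrec.evaluation import ConfusionMatrix, confusion, metrics, roc


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 3, 3, 2])
        cm = confusion(y, y)
        assert np.array_equal(np.diag(cm.counts), [1, 1, 2, 2])
        assert cm.counts.sum() == np.trace(cm.counts)

    def test_antidiagonal_pair(self):
        cm = confusion([0, 1], [1, 0])
        assert cm.counts[0, 1] == 1 and cm.counts[1, 0] == 1
        assert np.trace(cm.counts) == 0

    def test_matches_dictionary_tally(self, rng):
        y_true = rng.integers(0, 4, 500)
        y_pred = rng.integers(0, 4, 500)
        cm = confusion(y_true, y_pred)
        tally = {}
        for t, p in zip(y_true, y_pred):
            tally[(t, p)] = tally.get((t, p), 0) + 1
        for t in range(4):
            for p in range(4):
                assert cm.counts[t, p] == tally.get((t, p), 0)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [0])
        with pytest.raises(ValueError, match="codes outside"):
            confusion([0, 5], [0, 1])


class TestMetrics:
    def test_perfect_is_all_ones(self, rng):
        y = rng.integers(0, 4, 100)
        r = metrics(confusion(y, y))
        assert r.accuracy == r.precision == r.recall == r.f1 == 1.0

    def test_binary_embedded_direct_substitution(self):
        # TP=3, FN=1 / FP=1, TN=5 embedded in classes {0, 1}
        cm = ConfusionMatrix(np.array([[3, 1, 0, 0], [1, 5, 0, 0],
                                       [0, 0, 0, 0], [0, 0, 0, 0]]))
        r = metrics(cm)
        c0 = r.per_class[0]
        assert c0["tp"] == 3 and c0["fp"] == 1 and c0["fn"] == 1 and c0["tn"] == 5
        assert c0["accuracy"] == pytest.approx(0.8)
        assert c0["precision"] == pytest.approx(0.75)
        assert c0["recall"] == pytest.approx(0.75)
        assert c0["f1"] == pytest.approx(0.75)

    def test_macro_recall_equals_loop_oracle(self, rng):
        for _ in range(50):
            cm = ConfusionMatrix(rng.integers(0, 20, size=(4, 4)))
            if cm.total == 0:
                continue
            r = metrics(cm)
            recalls = []
            for c in range(4):
                row = cm.counts[c].sum()
                recalls.append(cm.counts[c, c] / row if row else 0.0)
            assert r.recall == pytest.approx(np.mean(recalls), abs=1e-12)

    def test_sample_order_invariance(self, rng):
        y_true = rng.integers(0, 4, 300)
        y_pred = rng.integers(0, 4, 300)
        perm = rng.permutation(300)
        a = metrics(confusion(y_true, y_pred))
        b = metrics(confusion(y_true[perm], y_pred[perm]))
        assert a.accuracy == b.accuracy and a.f1 == b.f1

    def test_recall_invariant_to_class_duplication(self, rng):
        """Duplicating one class's samples leaves every per-class recall (a
        truth-conditional rate) unchanged. Precision is *not* invariant: the
        duplicated class contributes extra false positives to other columns."""
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        dup = y_true == 2
        a = metrics(confusion(y_true, y_pred))
        b = metrics(confusion(np.concatenate([y_true, y_true[dup]]),
                              np.concatenate([y_pred, y_pred[dup]])))
        assert b.recall == pytest.approx(a.recall)
        for c in range(4):
            assert b.per_class[c]["recall"] == pytest.approx(a.per_class[c]["recall"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix(np.zeros((4, 4), dtype=int)))

    def test_no_predicted_positives_warns_zero_precision(self, caplog):
        cm = confusion([0, 0, 1, 1], [1, 1, 1, 1])
        r = metrics(cm)
        assert r.per_class[0]["precision"] == 0.0


def _mann_whitney_auc(scores, labels):
    """AUC = U / (n_pos * n_neg), with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def _probs(self, scores):
        p = np.column_stack([scores, 1 - scores, np.zeros_like(scores),
                             np.zeros_like(scores)])
        return p

    def test_perfectly_ranked_auc_one(self):
        y = np.array([1, 1, 0, 0, 2, 3])
        probs = np.full((6, 4), 1e-9)
        for i, c in enumerate(y):
            probs[i, c] = 1.0
        probs /= probs.sum(axis=1, keepdims=True)
        rs = roc(probs, y)
        assert all(a == pytest.approx(1.0) for a in rs.auc_per_class.values())

    def test_constant_scores_chance(self):
        y = np.array([0, 0, 1, 1, 2, 3])
        probs = np.full((6, 4), 0.25)
        rs = roc(probs, y)
        assert all(a == pytest.approx(0.5) for a in rs.auc_per_class.values())
        assert rs.mean_auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney(self, rng):
        scores = rng.random(20)
        y = (rng.random(20) > 0.5).astype(int)
        if y.sum() in (0, 20):
            y[0] = 1 - y[0]
        probs = self._probs(scores)
        y4 = np.where(y == 1, 0, 1)           # class 0 = positive
        rs = roc(probs, y4)
        assert rs.auc_per_class[0] == pytest.approx(
            _mann_whitney_auc(scores, y), abs=1e-12)

    def test_auc_mann_whitney_small_instances_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            scores = rng.integers(0, 4, n) / 3.0       # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            probs = self._probs(scores)
            y4 = np.where(labels == 1, 0, 1)
            rs = roc(probs, y4)
            assert rs.auc_per_class[0] == pytest.approx(
                _mann_whitney_auc(scores, labels), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        probs = rng.dirichlet(np.ones(4), size=50)
        y = rng.integers(0, 4, 50)
        rs = roc(probs, y)
        for fpr, tpr in rs.per_class_curves.values():
            assert fpr[0] == 0 and tpr[0] == 0
            assert fpr[-1] == 1 and tpr[-1] == 1
            assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_absent_class_skipped(self, rng):
        probs = rng.dirichlet(np.ones(4), size=30)
        y = rng.integers(0, 3, 30)            # class 3 never occurs
        rs = roc(probs, y)
        assert 3 not in rs.auc_per_class
        assert set(rs.per_class_curves) == {0, 1, 2}

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            roc(np.ones((4, 4)), [0, 1, 2, 3])
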