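"""Feature fusion, detection metrics (with the pairwise AUC oracle), and
the ablation harness."""

import numpy as np
import pytest

from drdetect.fusion import (ablation_suite, evaluate, fuse, reports_table,
                             train_classifier)
from drdetect.lesions import LesionCounts


class _FixedScores:
    """Stub classifier returning preset hard labels and scores."""

    def __init__(self, labels, scores=None):
        self._labels = np.asarray(labels)
        self._scores = np.asarray(scores if scores is not None else labels,
                                  dtype=float)

    def predict(self, X):
        return self._labels

    def predict_proba(self, X):
        return np.column_stack([1 - self._scores, self._scores])


def _auc_oracle(y, scores):
    """Brute-force pairwise Mann-Whitney AUC with midrank ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_fused_lengths_match_backbone_dims():
    counts = LesionCounts(MA=1, EX=2, HEM=0)
    assert fuse(np.zeros(25088), counts).shape == (25091,)
    assert fuse(np.zeros(100352), counts).shape == (100355,)


def test_counts_only_vector():
    v = fuse(None, LesionCounts(MA=1, EX=2, HEM=0))
    np.testing.assert_array_equal(v, [1.0, 2.0, 0.0])


def test_fuse_requires_a_block():
    with pytest.raises(ValueError):
        fuse(None, None)


def test_fuse_block_order():
    v = fuse(np.array([9.0, 8.0]), np.array([1, 2, 3]))
    np.testing.assert_array_equal(v, [9.0, 8.0, 1.0, 2.0, 3.0])


def test_perfect_predictions_yield_unit_metrics():
    y = ["DR"] * 81 + ["healthy"] * 81
    clf = _FixedScores([1] * 81 + [0] * 81)
    report = evaluate(clf, np.zeros((162, 3)), y)
    assert report.accuracy_pct == 100.0
    assert report.precision == report.recall == report.f1 == 1.0
    assert report.auc == 1.0


def test_one_error_on_162_images_is_9938_percent():
    """TP=80, FN=1, TN=81, FP=0 -> accuracy 161/162 = 99.38%."""
    y = ["DR"] * 81 + ["healthy"] * 81
    pred = [1] * 80 + [0] + [0] * 81
    report = evaluate(_FixedScores(pred), np.zeros((162, 3)), y)
    assert report.confusion.TP == 80 and report.confusion.FN == 1
    assert report.confusion.TN == 81 and report.confusion.FP == 0
    assert report.accuracy_pct == pytest.approx(99.38, abs=0.005)


def test_identical_scores_give_half_auc():
    y = ["DR"] * 5 + ["healthy"] * 5
    clf = _FixedScores([1] * 5 + [0] * 5, scores=[0.5] * 10)
    assert evaluate(clf, np.zeros((10, 2)), y).auc == pytest.approx(0.5)


def test_auc_matches_pairwise_oracle(rng):
    """Trapezoidal ROC AUC equals the normalized Mann-Whitney statistic,
    including tied scores, on small instances."""
    for _ in range(10):
        n = int(rng.integers(6, 21))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        scores = np.round(rng.random(n), 1)   # coarse grid forces ties
        clf = _FixedScores((scores > 0.5).astype(int), scores=scores)
        report = evaluate(clf, np.zeros((n, 2)), y)
        assert report.auc == pytest.approx(_auc_oracle(y, scores))


def test_report_consistent_with_confusion():
    y = ["DR"] * 6 + ["healthy"] * 6
    pred = [1, 1, 1, 1, 0, 0] + [0, 0, 0, 0, 0, 1]
    r = evaluate(_FixedScores(pred), np.zeros((12, 2)), y)
    cc = r.confusion
    assert r.accuracy_pct == pytest.approx(100 * (cc.TP + cc.TN) / cc.total)
    assert r.precision == pytest.approx(cc.TP / (cc.TP + cc.FP))
    assert r.recall == pytest.approx(cc.TP / (cc.TP + cc.FN))


def test_single_class_training_rejected():
    with pytest.raises(ValueError):
        train_classifier(np.zeros((4, 2)), ["DR"] * 4)


def test_single_class_test_leaves_auc_undefined():
    X = np.array([[3.0], [0.0], [2.0], [0.0]])
    clf = train_classifier(X, ["DR", "healthy", "DR", "healthy"], seed=0)
    report = evaluate(clf, np.array([[2.5]]), ["DR"])
    assert report.auc is None


def test_classifier_deterministic_under_seed(rng):
    X = rng.random((30, 5))
    y = ["DR" if v > 0.5 else "healthy" for v in X[:, 0]]
    p1 = train_classifier(X, y, seed=3).predict(X)
    p2 = train_classifier(X, y, seed=3).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_count_features_separate_synthetic_classes(rng):
    """Lesion presence defines the DR class, so counts alone classify a
    held-out split almost perfectly."""
    def make(n):
        y, C = [], []
        for i in range(n):
            dr = i % 2 == 0
            counts = [rng.integers(1, 5) if dr else 0 for _ in range(3)]
            if dr and sum(counts) == 0:
                counts[0] = 1
            C.append(counts)
            y.append("DR" if dr else "healthy")
        return np.array(C, dtype=float), y

    Xtr, ytr = make(40)
    Xte, yte = make(20)
    clf = train_classifier(Xtr, ytr, seed=0)
    report = evaluate(clf, Xte, yte)
    assert report.accuracy_pct >= 95.0


def test_ablation_enumerates_requested_subsets(rng):
    n_tr, n_te = 24, 12
    def blocks(n):
        # half healthy (all-zero counts), half DR (at least one lesion)
        lesions = np.zeros((n, 3))
        lesions[n // 2:] = rng.integers(1, 4, (n - n // 2, 3))
        return {"vgg16": rng.random((n, 8)),
                "resnet50": rng.random((n, 6)),
                "lesions": lesions}
    btr, bte = blocks(n_tr), blocks(n_te)
    ytr = ["DR" if btr["lesions"][i].sum() > 0 else "healthy"
           for i in range(n_tr)]
    yte = ["DR" if bte["lesions"][i].sum() > 0 else "healthy"
           for i in range(n_te)]
    reports = ablation_suite(btr, ytr, bte, yte, seed=0)
    expected = {"vgg16", "resnet50", "lesions", "vgg16+resnet50",
                "vgg16+lesions", "resnet50+lesions",
                "vgg16+resnet50+lesions", "ma", "ex", "hem", "ma+ex+hem"}
    assert expected <= set(reports)
    table = reports_table(reports)
    assert {"Classifier", "Accuracy %", "Precision", "Recall", "F1-score",
            "AUC"} <= set(table.columns)
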