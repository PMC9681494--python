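"""Flat feature fusion, gradient-boosted DR classification, detection
metrics, and the feature-ablation harness.

A fused vector is the concatenation [deep features || MA count || EX
count || HEM count]: 25,088 + 3 = 25,091 dims with VGG-16 features,
100,352 + 3 = 100,355 with ResNet-50. Lesion counts enter unscaled —
gradient-boosted trees are scale-invariant. The classifier is XGBoost
with library defaults and a fixed seed; any scikit-learn-style estimator
can be plugged in instead.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import xgboost
from sklearn.metrics import roc_auc_score

from .lesions import ConfusionCounts, LesionCounts, metrics_from_confusion

POSITIVE_LABEL = "DR"
LESION_ORDER = ("MA", "EX", "HEM")


@dataclasses.dataclass
class EvalReport:
    """Image-level detection performance of one feature subset."""
    feature_subset: str
    confusion: ConfusionCounts
    accuracy_pct: float
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None
    classifier: str = "xgboost"

    def as_row(self) -> dict:
        return {
            "Classifier": self.classifier,
            "Features": self.feature_subset,
            "Accuracy %": round(self.accuracy_pct, 2),
            "Precision": self.precision,
            "Recall": self.recall,
            "F1-score": self.f1,
            "AUC": self.auc,
        }


def fuse(deep: np.ndarray | None, counts: LesionCounts | np.ndarray | None,
         subset: str | None = None) -> np.ndarray:
    """Concatenate feature blocks in the fixed order [deep || MA || EX ||
    HEM]. At least one block must be present."""
    if deep is None and counts is None:
        raise ValueError("at least one feature block must be present")
    blocks = []
    if deep is not None:
        blocks.append(np.asarray(deep, dtype=np.float64).ravel())
    if counts is not None:
        arr = counts.as_array() if isinstance(counts, LesionCounts) \
            else np.asarray(counts, dtype=np.float64).ravel()
        blocks.append(arr)
    return np.concatenate(blocks)


def _encode(labels) -> np.ndarray:
    """Map labels to {0, 1}: the string "DR" (or any nonzero number) is
    the positive class, "healthy" (or 0) the negative."""
    out = []
    for lab in labels:
        if isinstance(lab, str):
            out.append(1 if lab == POSITIVE_LABEL else 0)
        else:
            out.append(int(lab != 0))
    return np.asarray(out, dtype=np.int64)


def train_classifier(X, labels, seed: int = 0, params: dict | None = None,
                     classifier=None):
    """Fit the detection classifier (XGBoost, library defaults, fixed
    seed). ``classifier`` is a pluggable seam for any estimator with
    fit/predict/predict_proba."""
    X = np.asarray(X, dtype=np.float64)
    y = _encode(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if classifier is None:
        classifier = xgboost.XGBClassifier(random_state=seed,
                                           **(params or {}))
    classifier.fit(X, y)
    return classifier


def evaluate(classifier, X, labels, feature_subset: str = "") -> EvalReport:
    """Score a trained classifier on held-out images.

    Confusion counts come from hard predictions; AUC from ranking the
    positive-class scores (trapezoidal ROC integral, midrank ties). A
    single-class test set leaves AUC undefined (None).
    """
    X = np.asarray(X, dtype=np.float64)
    y = _encode(labels)
    pred = np.asarray(classifier.predict(X)).astype(np.int64)
    cc = ConfusionCounts(
        TP=int(((pred == 1) & (y == 1)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()))
    m = metrics_from_confusion(cc)
    if len(np.unique(y)) < 2:
        auc = None
    else:
        if hasattr(classifier, "predict_proba"):
            scores = classifier.predict_proba(X)[:, 1]
        else:
            scores = pred.astype(np.float64)
        auc = float(roc_auc_score(y, scores))
    return EvalReport(
        feature_subset=feature_subset,
        confusion=cc,
        accuracy_pct=100.0 * m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        auc=auc,
        classifier=type(classifier).__name__.lower())


def _subset_matrix(blocks: dict, names) -> np.ndarray:
    return np.hstack([np.asarray(blocks[n], dtype=np.float64) for n in names])


def ablation_suite(train_blocks: dict, train_labels, test_blocks: dict,
                   test_labels, seed: int = 0, classifier_factory=None) -> dict:
    """Train and evaluate one classifier per feature subset.

    ``*_blocks`` map block names to per-image matrices: deep-feature
    blocks (e.g. "vgg16", "resnet50") and a "lesions" block of the three
    counts. Reports cover every non-empty combination of the top-level
    blocks, each lesion count alone ("ma", "ex", "hem"), and the three
    counts combined ("ma+ex+hem", identical input to "lesions").
    """
    names = list(train_blocks)
    if "lesions" in train_blocks:
        lesions_tr = np.asarray(train_blocks["lesions"], dtype=np.float64)
        lesions_te = np.asarray(test_blocks["lesions"], dtype=np.float64)
        per_lesion_tr = {cls.lower(): lesions_tr[:, [i]]
                         for i, cls in enumerate(LESION_ORDER)}
        per_lesion_te = {cls.lower(): lesions_te[:, [i]]
                         for i, cls in enumerate(LESION_ORDER)}
    else:
        per_lesion_tr = per_lesion_te = {}

    subsets: list[tuple[str, list[str]]] = []
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            subsets.append(("+".join(combo), list(combo)))

    reports = {}
    for key, combo in subsets:
        Xtr = _subset_matrix(train_blocks, combo)
        Xte = _subset_matrix(test_blocks, combo)
        clf = (classifier_factory() if classifier_factory
               else None)
        fitted = train_classifier(Xtr, train_labels, seed=seed,
                                  classifier=clf)
        reports[key] = evaluate(fitted, Xte, test_labels, feature_subset=key)

    for key in per_lesion_tr:
        fitted = train_classifier(per_lesion_tr[key], train_labels, seed=seed,
                                  classifier=(classifier_factory()
                                              if classifier_factory else None))
        reports[key] = evaluate(fitted, per_lesion_te[key], test_labels,
                                feature_subset=key)
    if per_lesion_tr:
        fitted = train_classifier(lesions_tr, train_labels, seed=seed,
                                  classifier=(classifier_factory()
                                              if classifier_factory else None))
        reports["ma+ex+hem"] = evaluate(fitted, lesions_te, test_labels,
                                        feature_subset="ma+ex+hem")
    return reports


def reports_table(reports: dict) -> pd.DataFrame:
    """Render EvalReports as a table with the standard metric columns."""
    return pd.DataFrame([r.as_row() for r in reports.values()])
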