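"""Binarization, contour-based lesion counting (vs. the connected-
component oracle), and segmentation metric closed forms."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import label as cc_label

from drdetect.lesions import (ConfusionCounts, binarize, count_lesions,
                              counts_from_masks, metrics_from_confusion,
                              seg_metrics)
from drdetect.synthetic import LESION_CLASSES, SynthSpec, generate_image


def test_binarize_constant_maps():
    assert (binarize(np.full((8, 8), 0.6)) == 1).all()
    assert (binarize(np.full((8, 8), 0.4)) == 0).all()


def test_binarize_idempotent_on_binary(rng):
    m = (rng.random((16, 16)) > 0.5).astype(float)
    np.testing.assert_array_equal(binarize(m), m.astype(np.uint8))


def test_binarize_rejects_out_of_range():
    with pytest.raises(ValueError):
        binarize(np.full((4, 4), 1.5))


def test_count_empty_mask_is_zero():
    assert count_lesions(np.zeros((64, 64), dtype=np.uint8)) == 0


def test_count_three_separated_disks():
    mask = np.zeros((64, 64), dtype=np.uint8)
    for cy, cx in [(12, 12), (12, 40), (45, 26)]:
        rr, cc = draw_disk((cy, cx), 5, shape=mask.shape)
        mask[rr, cc] = 1
    assert count_lesions(mask) == 3


def test_overlapping_ellipses_count_once():
    mask = np.zeros((64, 64), dtype=np.uint8)
    for dy, dx, rot in [(0, 0, 0.3), (3, 2, 1.2), (-2, 4, 2.0)]:
        rr, cc = draw_ellipse(30 + dy, 30 + dx, 8, 5, shape=mask.shape,
                              rotation=rot)
        mask[rr, cc] = 1
    assert cc_label(mask).max() == 1
    assert count_lesions(mask) == 1


def test_border_touching_lesion_counted():
    mask = np.zeros((32, 32), dtype=np.uint8)
    rr, cc = draw_disk((0, 16), 6, shape=mask.shape)
    mask[rr, cc] = 1
    assert count_lesions(mask) == 1


def test_min_area_filter_drops_specks():
    mask = np.zeros((64, 64), dtype=np.uint8)
    rr, cc = draw_disk((20, 20), 6, shape=mask.shape)
    mask[rr, cc] = 1
    mask[50:52, 50:52] = 1   # 2x2 speck
    assert count_lesions(mask) == 2
    assert count_lesions(mask, min_area=10) == 1


def test_count_rejects_non_binary():
    with pytest.raises(ValueError):
        count_lesions(np.full((8, 8), 7, dtype=np.uint8))


def test_count_matches_component_oracle_on_generator_masks():
    for seed in range(15):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 5)) for c in LESION_CLASSES}
        _, masks, _ = generate_image(SynthSpec(lesion_counts=counts,
                                               rng_seed=300 + seed))
        for cls in LESION_CLASSES:
            assert count_lesions(masks[cls]) == cc_label(masks[cls] > 0).max()


def test_counts_from_masks_exact(dr_image):
    spec, _, masks, _ = dr_image
    counts = counts_from_masks(masks)
    assert (counts.MA, counts.EX, counts.HEM) == \
        (spec.lesion_counts["MA"], spec.lesion_counts["EX"],
         spec.lesion_counts["HEM"])


def test_perfect_overlap_gives_unit_metrics():
    m = np.zeros((16, 16), dtype=np.uint8)
    m[4:9, 4:9] = 1
    out = seg_metrics(m, m)
    for key in ("recall", "precision", "f1", "accuracy", "iou"):
        assert out[key] == 1.0


def test_disjoint_masks_zero_overlap_metrics():
    a = np.zeros((16, 16), dtype=np.uint8)
    b = np.zeros((16, 16), dtype=np.uint8)
    a[0:4, 0:4] = 1
    b[10:14, 10:14] = 1
    out = seg_metrics(a, b)
    assert out["recall"] == 0.0 and out["precision"] == 0.0
    assert out["iou"] == 0.0
    assert out["f1"] is None    # 0/0: undefined, reported explicitly


def test_confusion_closed_forms():
    # TP=3, FP=1, FN=1, TN=5
    out = metrics_from_confusion(ConfusionCounts(TP=3, FP=1, FN=1, TN=5))
    assert out["precision"] == 0.75
    assert out["recall"] == 0.75
    assert out["f1"] == pytest.approx(0.75)
    assert out["accuracy"] == 0.8


def test_empty_prediction_metrics_undefined():
    t = np.zeros((8, 8), dtype=np.uint8)
    out = seg_metrics(t, t)   # nothing predicted, nothing true
    assert out["recall"] is None and out["precision"] is None
    assert out["iou"] is None
    assert out["accuracy"] == 1.0


def test_f1_harmonic_mean_and_iou_bound(rng):
    """F1 equals the harmonic mean of reported P and R; IoU <= F1."""
    for _ in range(20):
        pred = (rng.random((24, 24)) > 0.6).astype(np.uint8)
        truth = (rng.random((24, 24)) > 0.6).astype(np.uint8)
        out = seg_metrics(pred, truth)
        if out["f1"] is None or out["iou"] is None:
            continue
        p, r = out["precision"], out["recall"]
        assert out["f1"] == pytest.approx(2 * p * r / (p + r))
        assert out["iou"] <= out["f1"] + 1e-12
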