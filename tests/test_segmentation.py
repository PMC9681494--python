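"""Segmentation model architecture, focal loss closed forms, and the
cross-validation protocol (on tiny configurations)."""

import numpy as np
import pytest

from drdetect.segmentation import (SegConfig, SegModel, build_model,
                                   focal_loss, train_cv)


@pytest.mark.parametrize("n,base", [(128, 2), (256, 1)])
def test_output_shape_matches_input(n, base):
    model = build_model(SegConfig(n=n, base_filters=base, seed=0))
    x = np.random.default_rng(0).random((1, n, n), dtype=np.float32)
    p = model.predict_patches(x)
    assert p.shape == (1, n, n)
    assert p.min() >= 0.0 and p.max() <= 1.0


def test_untrained_output_is_probability(rng):
    model = build_model(SegConfig(n=32, base_filters=4, seed=1))
    p = model.predict_patches(rng.random((4, 32, 32), dtype=np.float32))
    assert ((p >= 0) & (p <= 1)).all()


def test_patch_size_must_divide_16():
    with pytest.raises(ValueError):
        build_model(SegConfig(n=100))


def test_depth_is_fixed():
    with pytest.raises(ValueError):
        build_model(SegConfig(n=64, depth=4))


def test_focal_loss_closed_forms():
    # perfect prediction -> loss ~ 0
    assert focal_loss(np.array([1 - 1e-7]), np.array([1.0])) < 1e-6
    # p=0.5, y=1, gamma=2, alpha=0.25 -> 0.25 * 0.25 * ln 2 = 0.0433
    assert focal_loss(np.array([0.5]), np.array([1.0]), 2.0, 0.25) == \
        pytest.approx(0.25 * 0.25 * np.log(2), rel=1e-6)


def test_focal_reduces_to_half_bce(rng):
    """gamma=0, alpha=0.5 gives exactly half the binary cross-entropy."""
    p = rng.uniform(0.05, 0.95, 50)
    y = (rng.random(50) > 0.5).astype(float)
    bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
    assert focal_loss(p, y, gamma=0.0, alpha=0.5) == pytest.approx(bce / 2)


def test_focal_loss_clamps_degenerate_probabilities():
    assert np.isfinite(focal_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0])))


def test_cv_fold_sizes_and_retention(rng):
    """k=5 on 160 patches -> validation folds of 32 patches each; the
    retained model is the best-accuracy fold."""
    xs = rng.random((160, 16, 16), dtype=np.float32)
    ys = np.zeros((160, 16, 16), dtype=np.float32)
    ys[:, 4:8, 4:8] = (xs[:, 4:8, 4:8] > 0.5)
    cfg = SegConfig(n=16, base_filters=2, seed=0)
    result = train_cv(xs, ys, cfg)
    assert len(result.models) == 5
    assert len(result.fold_metrics) == 5
    for m in result.fold_metrics:
        assert m["confusion"].total == 32 * 16 * 16
    accs = [m["accuracy"] for m in result.fold_metrics]
    assert accs[result.best_fold] == max(accs)


def test_steps_per_epoch_arithmetic():
    # 128 training patches at batch 32 -> 4 steps per epoch
    assert max(1, 128 // SegConfig().batch_size) == 4


def test_train_cv_warns_on_empty_foreground(rng):
    xs = rng.random((20, 16, 16), dtype=np.float32)
    ys = np.zeros((20, 16, 16), dtype=np.float32)
    cfg = SegConfig(n=16, base_filters=2, epochs=1, k_folds=5, seed=0)
    with pytest.warns(UserWarning):
        result = train_cv(xs, ys, cfg)
    for m in result.fold_metrics:
        assert m["recall"] is None           # no true foreground: undefined
        assert m["iou"] in (None, 0.0)       # None unless spurious positives


def test_inference_deterministic(rng):
    model = build_model(SegConfig(n=32, base_filters=4, seed=2))
    x = rng.random((3, 32, 32), dtype=np.float32)
    np.testing.assert_array_equal(model.predict_patches(x),
                                  model.predict_patches(x))


def test_save_load_round_trip(tmp_path, rng):
    model = build_model(SegConfig(n=32, base_filters=4, seed=3), "EX")
    x = rng.random((2, 32, 32), dtype=np.float32)
    model.save(tmp_path / "seg_ex")
    restored = SegModel.load(tmp_path / "seg_ex")
    assert restored.lesion_class == "EX"
    np.testing.assert_array_equal(model.predict_patches(x),
                                  restored.predict_patches(x))


def test_predict_image_shape_and_determinism(rng):
    model = build_model(SegConfig(n=32, base_filters=4, seed=4))
    img = (rng.random((80, 90)) * 255).astype(np.uint8)
    pm = model.predict_image(img)
    assert pm.shape == (80, 90)
    assert pm.min() >= 0 and pm.max() <= 1
    np.testing.assert_array_equal(pm, model.predict_image(img))
    with pytest.raises(ValueError):
        model.predict_image(img[:20, :20])
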