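"""Per-lesion binary segmentation: model construction, focal loss,
k-fold cross-validated training, and full-image prediction.

One independent model is trained per lesion class. Patches enter as
(batch, n, n, 1) tensors scaled to [0, 1]; the loss is binary focal
cross-entropy (the foreground/background imbalance of lesion masks makes
plain cross-entropy collapse to the background class). K-fold
cross-validation (default k = 5) runs over the patches; per-fold pixel
metrics are computed on the validation patches and the fold with the
best validation accuracy is retained.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.model_selection import GroupKFold, KFold

from .nn.unet import UNet
from .patches import augment, reconstruct, tile
from .preprocess import EnhancedImage
from .lesions import binarize, seg_metrics, ConfusionCounts, metrics_from_confusion, _ratio

EPS = 1e-7


@dataclasses.dataclass
class SegConfig:
    """Training configuration for one lesion class.

    ``n`` is the square patch size in pixels — 128 for microaneurysms
    (small lesions), 256 for exudates and hemorrhages at full scale;
    desk-scale runs use 64. Five convolution levels imply ``n`` divisible
    by 16. ``augment_prob`` is the chance that a training patch is passed
    through the random flip/rotation augmenter.
    """

    n: int = 256
    base_filters: int = 16
    depth: int = 5
    batch_size: int = 32
    epochs: int = 3
    k_folds: int = 5
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    learning_rate: float = 1e-3
    augment_prob: float = 0.5
    group_folds: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.depth != 5:
            raise ValueError("the architecture is fixed at 5 convolution levels")
        if self.n % 16 != 0:
            raise ValueError(f"patch size {self.n} must be divisible by 16")


def desk_config(lesion_class: str, seed: int = 0) -> SegConfig:
    """Scaled-down configuration used by the synthetic evaluation harness:
    32-px patches, 8 base filters, and a learning rate suited to a model
    this small."""
    return SegConfig(n=32, base_filters=8, learning_rate=1e-2, seed=seed)


def focal_loss(p, y, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Mean binary focal cross-entropy.

    Per pixel: ``alpha * (1-p)^gamma * (-log p)`` for y = 1 and
    ``(1-alpha) * p^gamma * (-log(1-p))`` for y = 0. With gamma = 0 and
    alpha = 0.5 this is half the standard binary cross-entropy.
    Probabilities are clamped to [eps, 1-eps].
    """
    p = np.clip(np.asarray(p, dtype=np.float64), EPS, 1 - EPS)
    y = np.asarray(y, dtype=np.float64)
    loss = (alpha * (1 - p) ** gamma * (-np.log(p)) * y
            + (1 - alpha) * p ** gamma * (-np.log(1 - p)) * (1 - y))
    return float(loss.mean())


def _focal_grad(p, y, gamma: float, alpha: float) -> np.ndarray:
    """d(mean focal loss)/dp, elementwise."""
    p = np.clip(np.asarray(p, dtype=np.float64), EPS, 1 - EPS)
    y = np.asarray(y, dtype=np.float64)
    pos = alpha * (gamma * (1 - p) ** (gamma - 1) * np.log(p)
                   - (1 - p) ** gamma / p)
    neg = (1 - alpha) * (gamma * p ** (gamma - 1) * (-np.log(1 - p))
                         + p ** gamma / (1 - p))
    return (pos * y + neg * (1 - y)) / p.size


class SegModel:
    """A trained segmentation network for one lesion class."""

    def __init__(self, cfg: SegConfig, lesion_class: str):
        cfg.validate()
        self.cfg = cfg
        self.lesion_class = lesion_class
        self.net = UNet(cfg.n, base_filters=cfg.base_filters, seed=cfg.seed)

    def predict_patches(self, patches: np.ndarray) -> np.ndarray:
        """(N, n, n) patches in [0, 255] or [0, 1] -> (N, n, n) probabilities."""
        x = np.asarray(patches, dtype=np.float32)
        if x.max() > 1.5:
            x = x / 255.0
        # center to [-1, 1]; intensities enter the net zero-mean
        return self.net.predict(x * 2.0 - 1.0)

    def predict_image(self, enhanced, stride: int | None = None) -> np.ndarray:
        """Tile an enhanced image, batch-predict, and reconstruct the
        full-resolution probability map (mean over overlaps)."""
        arr = enhanced.pixels if isinstance(enhanced, EnhancedImage) else np.asarray(enhanced)
        if min(arr.shape[:2]) < self.cfg.n:
            raise ValueError(f"image {arr.shape} smaller than patch size {self.cfg.n}")
        ps = tile(arr, self.cfg.n, stride or self.cfg.n // 2)
        probs = self.predict_patches(np.stack(ps.patches))
        return reconstruct(list(probs), ps.placements, *ps.source_shape)

    def save(self, path) -> None:
        path = Path(path)
        self.net.save_weights(path.with_suffix(".npz"))
        sidecar = {"lesion_class": self.lesion_class,
                   "config": dataclasses.asdict(self.cfg)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "SegModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(SegConfig(**sidecar["config"]), sidecar["lesion_class"])
        model.net.load_weights(path.with_suffix(".npz"))
        return model


def build_model(cfg: SegConfig, lesion_class: str = "EX") -> SegModel:
    return SegModel(cfg, lesion_class)


@dataclasses.dataclass
class TrainResult:
    models: list                # one SegModel per fold
    fold_metrics: list          # per-fold validation metric dicts
    best_fold: int              # index of the retained model

    @property
    def best_model(self) -> SegModel:
        return self.models[self.best_fold]


def _fold_validation_metrics(model: SegModel, xs: np.ndarray,
                             ys: np.ndarray) -> dict:
    probs = model.predict_patches(xs)
    pred = binarize(probs)
    truth = (ys > 0.5).astype(np.uint8)
    cc = ConfusionCounts(
        TP=int((pred & truth).sum()), FP=int((pred & (1 - truth)).sum()),
        FN=int(((1 - pred) & truth).sum()), TN=int(((1 - pred) & (1 - truth)).sum()))
    out = metrics_from_confusion(cc)
    out["iou"] = _ratio(cc.TP, cc.TP + cc.FP + cc.FN)
    out["confusion"] = cc
    return out


def train_cv(image_patches, mask_patches, cfg: SegConfig,
             lesion_class: str = "EX", groups=None) -> TrainResult:
    """K-fold cross-validated training over index-aligned image/mask
    patches.

    Steps per epoch are the number of training patches per fold divided
    by the batch size. A fraction of the training patches (``augment_prob``
    each) receives a random flip/rotation, applied identically to image
    and mask. The fold whose validation accuracy is highest is retained.
    Folds with no foreground pixels are trained anyway but their
    undefined metrics are reported as None with a warning.
    """
    cfg.validate()
    xs = np.stack([np.asarray(p, dtype=np.float32) for p in image_patches])
    ys = np.stack([(np.asarray(p) > 0).astype(np.float32) for p in mask_patches])
    if xs.max() > 1.5:
        xs = xs / 255.0
    n_patches = len(xs)
    if n_patches < cfg.k_folds:
        raise ValueError(f"{n_patches} patches cannot form {cfg.k_folds} folds")

    if cfg.group_folds and groups is not None:
        splitter = GroupKFold(n_splits=cfg.k_folds)
        splits = splitter.split(xs, groups=groups)
    else:
        splitter = KFold(n_splits=cfg.k_folds, shuffle=True,
                         random_state=cfg.seed)
        splits = splitter.split(xs)

    models, fold_metrics = [], []
    for fold, (tr_idx, va_idx) in enumerate(splits):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, fold]))
        model = SegModel(dataclasses.replace(cfg, seed=cfg.seed + fold),
                         lesion_class)
        opt = model.net.optimizer(cfg.learning_rate)

        xtr, ytr = xs[tr_idx].copy(), ys[tr_idx].copy()
        for i in range(len(xtr)):
            if rng.random() < cfg.augment_prob:
                img8 = np.clip(np.rint(xtr[i] * 255), 0, 255).astype(np.uint8)
                msk8 = (ytr[i] > 0).astype(np.uint8)
                a_img, a_msk = augment(img8, msk8, rng)
                xtr[i] = a_img.astype(np.float32) / 255.0
                ytr[i] = a_msk.astype(np.float32)

        if ytr.sum() == 0:
            warnings.warn(f"fold {fold}: no foreground pixels in training "
                          "patches", stacklevel=2)

        steps = max(1, len(xtr) // cfg.batch_size)
        order = np.arange(len(xtr))
        for _epoch in range(cfg.epochs):
            rng.shuffle(order)
            for s in range(steps):
                idx = order[s * cfg.batch_size:(s + 1) * cfg.batch_size]
                xb = xtr[idx][..., None] * 2.0 - 1.0
                yb = ytr[idx]
                p = model.net.forward(xb)
                dp = _focal_grad(p, yb, cfg.focal_gamma, cfg.focal_alpha)
                model.net.backward((dp * p * (1 - p)).astype(np.float32))
                opt.step()

        metrics = _fold_validation_metrics(model, xs[va_idx], ys[va_idx])
        if ys[va_idx].sum() == 0:
            warnings.warn(f"fold {fold}: validation patches contain no "
                          "foreground; recall/IoU undefined", stacklevel=2)
        models.append(model)
        fold_metrics.append(metrics)

    best = int(np.argmax([m["accuracy"] if m["accuracy"] is not None else -1
                          for m in fold_metrics]))
    return TrainResult(models=models, fold_metrics=fold_metrics, best_fold=best)
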