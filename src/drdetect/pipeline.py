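"""End-to-end orchestration: synthesize or ingest a dataset, enhance,
train per-lesion segmentation models, extract lesion and deep features,
fuse, train the detector, and evaluate.

A single ``RunConfig`` is the only source of parameters; every
stochastic stage derives its seed from the global seed, and each written
artifact carries the hash of the config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import features as tlf
from . import fusion, lesions, synthetic
from .preprocess import DEFAULT_CLIP, DEFAULT_GAMMA, enhance
from .io import load_image
from .patches import tile
from .segmentation import SegConfig, desk_config, train_cv
from .synthetic import LESION_CLASSES, SynthSpec

log = logging.getLogger("drdetect")

MASK_COLS = {"MA": "ma_mask", "EX": "ex_mask", "HEM": "hem_mask"}


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    manifest: str | None = None          # ingest instead of synthesizing
    n_train_healthy: int = 20
    n_train_dr: int = 20
    n_test_healthy: int = 10
    n_test_dr: int = 10
    clip_limit: float = DEFAULT_CLIP
    gamma: float = DEFAULT_GAMMA
    patch_n: int = 32
    patch_stride: int = 8
    base_filters: int = 8
    epochs: int = 3
    batch_size: int = 32
    k_folds: int = 5
    learning_rate: float = 1e-2
    backbones: tuple = ("resnet50",)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["backbones"] = list(self.backbones)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "backbones" in data:
            data["backbones"] = tuple(data["backbones"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def seg_config(self, lesion_class: str) -> SegConfig:
        return SegConfig(n=self.patch_n, base_filters=self.base_filters,
                         batch_size=self.batch_size, epochs=self.epochs,
                         k_folds=self.k_folds,
                         learning_rate=self.learning_rate,
                         seed=self.seed + {"MA": 1, "EX": 2, "HEM": 3}[lesion_class])


def _patches_for_class(manifest, cls: str, cfg: RunConfig):
    """Enhanced-image and mask patches for one lesion class, plus the
    source-image group of each patch."""
    img_patches, msk_patches, groups = [], [], []
    for i, row in manifest.iterrows():
        enhanced = enhance(load_image(row["image"]), clip_limit=cfg.clip_limit,
                           gamma=cfg.gamma)
        mask = load_image(row[MASK_COLS[cls]])
        ps_img = tile(enhanced.pixels, cfg.patch_n, cfg.patch_stride)
        ps_msk = tile(mask, cfg.patch_n, cfg.patch_stride)
        img_patches.extend(ps_img.patches)
        msk_patches.extend(ps_msk.patches)
        groups.extend([i] * len(ps_img.patches))
    return img_patches, msk_patches, groups


def train_segmenters(manifest, cfg: RunConfig) -> tuple[dict, dict]:
    """Train one cross-validated model per lesion class; return the
    retained models and their per-fold validation metrics."""
    models, cv_metrics = {}, {}
    for cls in LESION_CLASSES:
        t0 = time.time()
        imgs, msks, groups = _patches_for_class(manifest, cls, cfg)
        result = train_cv(imgs, msks, cfg.seg_config(cls), lesion_class=cls,
                          groups=groups)
        models[cls] = result.best_model
        cv_metrics[cls] = {
            "best_fold": result.best_fold,
            "folds": [{k: v for k, v in m.items() if k != "confusion"}
                      for m in result.fold_metrics],
        }
        log.info("trained %s segmenter on %d patches in %.1fs (best IoU %.3f)",
                 cls, len(imgs), time.time() - t0,
                 result.fold_metrics[result.best_fold]["iou"] or float("nan"))
    return models, cv_metrics


def lesion_count_matrix(manifest, models: dict, cfg: RunConfig) -> np.ndarray:
    """Predicted (n_images, 3) lesion-count features, model pipeline path."""
    rows = []
    for _, row in manifest.iterrows():
        counts = lesions.extract_features(
            load_image(row["image"]), models,
            clip_limit=cfg.clip_limit, gamma=cfg.gamma)
        rows.append(counts.as_array())
    return np.stack(rows)


def deep_feature_matrix(manifest, backbone: str, seed: int) -> np.ndarray:
    spec = tlf.BackboneSpec(architecture=backbone, weights="random", seed=seed)
    images = (load_image(row["image"]) for _, row in manifest.iterrows())
    return tlf.extract_batch(images, spec)


def run_full(cfg: RunConfig) -> dict:
    """Execute the whole pipeline and write artifacts plus a run summary
    (JSON, tagged with the config hash) under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log.info("run %s -> %s", chash, out)

    if cfg.manifest:
        manifest = synthetic.load_manifest(cfg.manifest)
        n_test = max(len(manifest) // 3, 2)
        train_manifest = manifest.iloc[:-n_test].reset_index(drop=True)
        test_manifest = manifest.iloc[-n_test:].reset_index(drop=True)
    else:
        train_manifest = synthetic.generate_dataset(
            cfg.n_train_healthy, cfg.n_train_dr, out / "train",
            template=SynthSpec(), seed=cfg.seed)
        test_manifest = synthetic.generate_dataset(
            cfg.n_test_healthy, cfg.n_test_dr, out / "test",
            template=SynthSpec(), seed=cfg.seed + 10_000)

    models, cv_metrics = train_segmenters(train_manifest, cfg)
    for cls, model in models.items():
        model.save(out / f"segmenter_{cls.lower()}")

    blocks_tr = {"lesions": lesion_count_matrix(train_manifest, models, cfg)}
    blocks_te = {"lesions": lesion_count_matrix(test_manifest, models, cfg)}
    for arch in cfg.backbones:
        blocks_tr[arch] = deep_feature_matrix(train_manifest, arch, cfg.seed)
        blocks_te[arch] = deep_feature_matrix(test_manifest, arch, cfg.seed)

    y_tr = list(train_manifest["label"])
    y_te = list(test_manifest["label"])
    reports = fusion.ablation_suite(blocks_tr, y_tr, blocks_te, y_te,
                                    seed=cfg.seed)

    table = fusion.reports_table(reports)
    table.to_csv(out / "ablation.csv", index=False)
    summary = {
        "config_hash": chash,
        "config": cfg.to_dict(),
        "segmentation_cv": cv_metrics,
        "reports": {k: {**r.as_row(),
                        "confusion": dataclasses.asdict(r.confusion)}
                    for k, r in reports.items()},
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
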