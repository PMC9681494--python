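"""Image and feature-matrix I/O helpers (PNG/JPEG/TIFF via Pillow)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image


def load_image(path) -> np.ndarray:
    """Read an image as a uint8 array (H x W x 3 for RGB, H x W for gray)."""
    with Image.open(path) as im:
        if im.mode not in ("RGB", "L"):
            im = im.convert("RGB")
        return np.asarray(im)


def save_image(path, arr: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)


def save_features(path, X: np.ndarray, meta: dict) -> None:
    """Persist a feature matrix as compressed binary with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), features=X)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_features(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        X = data["features"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return X, meta
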