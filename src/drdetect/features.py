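"""Flattened deep features from topless classification backbones.

Images are resized to the backbones' 224x224x3 input, normalized with
the canonical ImageNet channel statistics, propagated to the last
convolutional volume (7x7x512 for VGG-16, 7x7x2048 for ResNet-50), and
flattened row-major over (row, col, channel) — the order matters because
fused feature indices depend on it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize

from .nn.backbones import (INPUT_SIZE, TERMINAL_SHAPES, backbone_forward,
                           build_backbone)

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

FEATURE_LENGTHS = {arch: int(np.prod(shape))
                   for arch, shape in TERMINAL_SHAPES.items()}


@dataclasses.dataclass(frozen=True)
class BackboneSpec:
    """Which backbone to use and where its weights come from.

    ``weights='random'`` (seeded He init) exercises the architecture with
    no download; ``'imagenet'`` requires pretrained weights and raises if
    they are unavailable.
    """

    architecture: str = "vgg16"
    weights: str = "random"
    seed: int = 0

    @property
    def feature_length(self) -> int:
        return FEATURE_LENGTHS[self.architecture]


_WEIGHT_CACHE: dict = {}


def _weights_for(spec: BackboneSpec):
    key = (spec.architecture, spec.weights, spec.seed)
    if key not in _WEIGHT_CACHE:
        _WEIGHT_CACHE[key] = build_backbone(spec.architecture, spec.weights,
                                            spec.seed)
    return _WEIGHT_CACHE[key]


def prepare_input(img) -> np.ndarray:
    """RGB uint8 image of any size -> normalized (224, 224, 3) float32."""
    arr = getattr(img, "pixels", img)
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {arr.shape}")
    if arr.shape[:2] != (INPUT_SIZE, INPUT_SIZE):
        arr = resize(arr, (INPUT_SIZE, INPUT_SIZE, 3), order=1,
                     preserve_range=True, anti_aliasing=True)
    x = arr.astype(np.float32) / 255.0
    return (x - IMAGENET_MEAN) / IMAGENET_STD


def extract(img, spec: BackboneSpec) -> np.ndarray:
    """Flattened deep feature vector of one image (length 25,088 for
    VGG-16, 100,352 for ResNet-50)."""
    x = prepare_input(img)[None]
    vol = backbone_forward(x, _weights_for(spec))[0]
    return vol.reshape(-1).astype(np.float32)


def extract_batch(images, spec: BackboneSpec, progress: bool = False) -> np.ndarray:
    """Feature matrix (n_images, feature_length); images processed one at
    a time to bound memory."""
    rows = [extract(img, spec) for img in images]
    return np.stack(rows)
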