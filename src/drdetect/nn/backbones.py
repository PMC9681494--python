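"""Forward-only ("topless") image-classification backbones for feature
extraction: VGG-16 and ResNet-50 with their classifier heads removed.

Both expect 224x224x3 input and terminate at the last convolutional
volume — 7x7x512 for VGG-16 and 7x7x2048 for ResNet-50 — which callers
flatten into 25,088- and 100,352-dim feature vectors.

Weights are generated deterministically from a seed (He init). Pretrained
ImageNet weights require a network download and are therefore not bundled;
requesting them raises with a pointer to random-weight mode, in which the
architecture (and hence every dimension) is identical.
"""

from __future__ import annotations

import numpy as np

from .layers import F32, conv2d, he_init, maxpool

INPUT_SIZE = 224
TERMINAL_SHAPES = {"vgg16": (7, 7, 512), "resnet50": (7, 7, 2048)}

_VGG_BLOCKS = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
# (mid_channels, out_channels, n_blocks, first_stride) per ResNet stage
_RESNET_STAGES = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2),
                  (512, 2048, 3, 2)]


def _relu(x):
    return np.maximum(x, 0.0)


def _conv_w(rng, k, cin, cout):
    return he_init(rng, (k, k, cin, cout), k * k * cin)


def build_backbone(architecture: str, weights: str = "random", seed: int = 0):
    """Return the weight structure for an architecture.

    ``weights='random'`` draws a deterministic He-initialized parameter set
    from ``seed``; ``weights='imagenet'`` is rejected (no offline weight
    source) with a message suggesting random mode.
    """
    if architecture not in TERMINAL_SHAPES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if weights == "imagenet":
        raise RuntimeError(
            "imagenet-pretrained weights are not bundled and require a "
            "download; use weights='random' for architecture-only feature "
            "extraction")
    if weights != "random":
        raise ValueError(f"unknown weight source {weights!r}")
    rng = np.random.default_rng(seed)
    if architecture == "vgg16":
        layers = []
        cin = 3
        for cout, reps in _VGG_BLOCKS:
            block = []
            for _ in range(reps):
                block.append(_conv_w(rng, 3, cin, cout))
                cin = cout
            layers.append(block)
        return {"arch": "vgg16", "blocks": layers}
    # resnet50
    stem = _conv_w(rng, 7, 3, 64)
    stages = []
    cin = 64
    for mid, cout, reps, stride in _RESNET_STAGES:
        blocks = []
        for b in range(reps):
            s = stride if b == 0 else 1
            blk = {
                "w1": _conv_w(rng, 1, cin, mid),
                "w2": _conv_w(rng, 3, mid, mid),
                "w3": _conv_w(rng, 1, mid, cout),
                "stride": s,
            }
            if b == 0:
                blk["proj"] = _conv_w(rng, 1, cin, cout)
            blocks.append(blk)
            cin = cout
        stages.append(blocks)
    return {"arch": "resnet50", "stem": stem, "stages": stages}


def _vgg16_forward(x, weights):
    for block in weights["blocks"]:
        for W in block:
            x = _relu(conv2d(x, W, pad=1))
        x = maxpool(x, 2, 2)
    return x


def _resnet50_forward(x, weights):
    x = _relu(conv2d(x, weights["stem"], stride=2, pad=3))   # 224 -> 112
    x = maxpool(x, 3, 2, pad=1)                              # 112 -> 56
    for stage in weights["stages"]:
        for blk in stage:
            shortcut = x
            y = _relu(conv2d(x, blk["w1"]))
            y = _relu(conv2d(y, blk["w2"], stride=blk["stride"], pad=1))
            y = conv2d(y, blk["w3"])
            if "proj" in blk:
                shortcut = conv2d(x, blk["proj"], stride=blk["stride"])
            x = _relu(y + shortcut)
    return x


def backbone_forward(x: np.ndarray, weights: dict) -> np.ndarray:
    """Propagate a (N, 224, 224, 3) float32 batch to the terminal volume."""
    x = np.asarray(x, dtype=F32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != (INPUT_SIZE, INPUT_SIZE, 3):
        raise ValueError(f"backbone input must be (N, 224, 224, 3), got {x.shape}")
    if weights["arch"] == "vgg16":
        return _vgg16_forward(x, weights)
    return _resnet50_forward(x, weights)
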