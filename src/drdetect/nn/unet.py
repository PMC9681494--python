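"""Symmetric encoder-decoder segmentation network with skip connections.

Five convolution levels: four encoder blocks (2x conv3x3+ReLU, then 2x2
max-pool) feeding a bottleneck block, mirrored by four decoder blocks
(2x2 transpose conv + ReLU, channel concatenation with the matching
encoder output, 2x conv3x3+ReLU). A 1x1 convolution with sigmoid yields
a per-pixel foreground probability. Filter widths double per level from
``base_filters``. The spatial size must be divisible by 16 (four pooling
stages).
"""

from __future__ import annotations

import numpy as np

from .layers import F32, Adam, Conv2D, ConvTranspose2, MaxPool2, ReLU


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class UNet:
    def __init__(self, n: int, base_filters: int = 16, in_channels: int = 1,
                 seed: int = 0, out_bias: float = -2.0):
        if n % 16 != 0:
            raise ValueError(f"patch size {n} not divisible by 16")
        self.n = n
        self.base_filters = base_filters
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        f = base_filters
        enc_ch = [f, 2 * f, 4 * f, 8 * f]

        self.enc = []
        cin = in_channels
        for c in enc_ch:
            self.enc.append({
                "c1": Conv2D(cin, c, 3, rng), "r1": ReLU(),
                "c2": Conv2D(c, c, 3, rng), "r2": ReLU(),
                "pool": MaxPool2(),
            })
            cin = c
        self.bott = {
            "c1": Conv2D(cin, 16 * f, 3, rng), "r1": ReLU(),
            "c2": Conv2D(16 * f, 16 * f, 3, rng), "r2": ReLU(),
        }
        self.dec = []
        cin = 16 * f
        for c in reversed(enc_ch):
            self.dec.append({
                "up": ConvTranspose2(cin, c, rng), "ru": ReLU(),
                "c1": Conv2D(2 * c, c, 3, rng), "r1": ReLU(),
                "c2": Conv2D(c, c, 3, rng), "r2": ReLU(),
            })
            cin = c
        self.out = Conv2D(cin, 1, 1, rng)
        # start the output layer biased toward background: lesion masks are
        # overwhelmingly negative, and a low prior keeps early updates from
        # being dominated by the easy background class
        self.out.b[:] = out_bias

    # -- plumbing ---------------------------------------------------------

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.values())
        out.extend(self.bott.values())
        for blk in self.dec:
            out.extend(blk.values())
        out.append(self.out)
        return out

    def optimizer(self, lr: float) -> Adam:
        return Adam(self.layers(), lr=lr)

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, n, n, C) float32 in [0, 1] -> per-pixel probability."""
        x = np.asarray(x, dtype=F32)
        skips = []
        for blk in self.enc:
            s = blk["r2"].forward(blk["c2"].forward(
                blk["r1"].forward(blk["c1"].forward(x))))
            skips.append(s)
            x = blk["pool"].forward(s)
        x = self.bott["r2"].forward(self.bott["c2"].forward(
            self.bott["r1"].forward(self.bott["c1"].forward(x))))
        for blk, s in zip(self.dec, reversed(skips)):
            up = blk["ru"].forward(blk["up"].forward(x))
            x = np.concatenate([up, s], axis=-1)
            x = blk["r2"].forward(blk["c2"].forward(
                blk["r1"].forward(blk["c1"].forward(x))))
        z = self.out.forward(x)[..., 0]
        self._p = sigmoid(z)
        return self._p

    def backward(self, dz: np.ndarray) -> None:
        """Backprop from d(loss)/d(logit), shape (N, n, n)."""
        dx = self.out.backward(dz[..., None].astype(F32))
        dskips = []
        for blk in reversed(self.dec):
            d = blk["c1"].backward(blk["r1"].backward(
                blk["c2"].backward(blk["r2"].backward(dx))))
            c = blk["up"].W.shape[-1]
            d_up, d_skip = d[..., :c], d[..., c:]
            dskips.append(d_skip)
            dx = blk["up"].backward(blk["ru"].backward(d_up))
        dx = self.bott["c1"].backward(self.bott["r1"].backward(
            self.bott["c2"].backward(self.bott["r2"].backward(dx))))
        for blk, d_skip in zip(reversed(self.enc), reversed(dskips)):
            ds = blk["pool"].backward(dx) + d_skip
            dx = blk["c1"].backward(blk["r1"].backward(
                blk["c2"].backward(blk["r2"].backward(ds))))

    def predict(self, x: np.ndarray, chunk: int = 16) -> np.ndarray:
        """Inference in chunks to bound memory; returns (N, n, n) probs."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 3:
            x = x[..., None]
        parts = [self.forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(parts, axis=0)

    # -- persistence ------------------------------------------------------

    def state_arrays(self) -> dict:
        arrs = {}
        for i, layer in enumerate(self.layers()):
            for name, p, _ in layer.trainables():
                arrs[f"l{i}_{name}"] = p
        return arrs

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for key, target in self.state_arrays().items():
                target[...] = data[key]
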