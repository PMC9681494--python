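"""Convolutional layers with manual backprop, plus the Adam optimizer.

Convolutions are computed by gathering sliding windows (im2col) and
contracting with the kernel via einsum, which routes to BLAS matmul.
Backward passes recompute the window view from the cached input rather
than caching it, trading a little compute for a large memory saving.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


def _windows(x: np.ndarray, kh: int, kw: int, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Sliding (kh, kw) windows of an NHWC array -> (N, Ho, Wo, C, kh, kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))
    if stride > 1:
        v = v[:, ::stride, ::stride]
    return v


def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray | None = None,
           stride: int = 1, pad: int = 0) -> np.ndarray:
    """Cross-correlation of NHWC input with a (kh, kw, Cin, Cout) kernel."""
    kh, kw = W.shape[:2]
    v = _windows(x, kh, kw, stride, pad)
    y = np.einsum("nhwckl,klco->nhwo", v, W, optimize=True)
    if b is not None:
        y += b
    return y


def maxpool(x: np.ndarray, k: int, stride: int, pad: int = 0) -> np.ndarray:
    """Forward-only max pooling (used by the frozen feature backbones)."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)),
                   constant_values=-np.inf)
    v = _windows(x, k, k, stride)
    return v.max(axis=(-2, -1))


class Layer:
    def trainables(self):
        return []


class Conv2D(Layer):
    """Stride-1 'same' convolution, kernel size 3 or 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        self.W = he_init(rng, (k, k, cin, cout), k * k * cin)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = None
        self.db = None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return conv2d(x, self.W, self.b, pad=self.k // 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        v = _windows(self._x, self.k, self.k, 1, self.k // 2)
        self.dW = np.einsum("nhwckl,nhwo->klco", v, dy, optimize=True)
        self.db = dy.sum(axis=(0, 1, 2))
        # gradient w.r.t. input: correlate dy with the flipped kernel
        Wf = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2))
        return conv2d(dy, Wf, pad=self.k // 2)

    def trainables(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._m = x > 0
        return x * self._m

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._m


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Ties share the gradient equally."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        self._mask = xr == y[:, :, None, :, None, :]
        self._cnt = self._mask.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self._mask * (dy[:, :, None, :, None, :] / self._cnt)
        return g.reshape(self._shape).astype(F32)


class ConvTranspose2(Layer):
    """2x2 transpose convolution with stride 2 (non-overlapping upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = he_init(rng, (2, 2, cin, cout), cin)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = None
        self.db = None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, c = x.shape
        cout = self.W.shape[-1]
        y = np.einsum("nhwc,abco->nhawbo", x, self.W, optimize=True)
        return y.reshape(n, 2 * h, 2 * w, cout) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, cout = dy.shape
        dyr = dy.reshape(n, h2 // 2, 2, w2 // 2, 2, cout)
        self.dW = np.einsum("nhwc,nhawbo->abco", self._x, dyr, optimize=True)
        self.db = dy.sum(axis=(0, 1, 2))
        return np.einsum("nhawbo,abco->nhwc", dyr, self.W, optimize=True)

    def trainables(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Adam:
    """Adaptive-moment gradient descent over a fixed list of layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.trainables()]
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.trainables():
                key = (i, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
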