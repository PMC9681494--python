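"""Contrast-enhancement chain for fundus images.

Four steps, applied in order: (1) zero the non-eye background margins,
(2) extract the green channel (highest vessel/lesion contrast), (3)
contrast-limited adaptive histogram equalization on an 8x8 tile grid,
(4) gamma correction (default gamma = 0.8, a brightening map).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .synthetic import FundusImage

CLAHE_TILES = 8          # 8x8 tile grid
DEFAULT_CLIP = 2.0       # contrast clip, in multiples of the uniform bin height
DEFAULT_GAMMA = 0.8


@dataclasses.dataclass
class EnhancedImage:
    pixels: np.ndarray          # H x W uint8
    steps: list                 # ordered record of applied operations


def _as_rgb(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got {arr.shape}")
    return arr


def eye_disc_mask(rgb: np.ndarray) -> np.ndarray | None:
    """Detect the circular eye region: Otsu threshold on grayscale, keep
    the largest connected component, close small gaps (5x5)."""
    gray = rgb2gray(rgb)
    if gray.max() == gray.min():
        return None
    thr = threshold_otsu(gray)
    fg = gray > thr
    if not fg.any():
        return None
    lab = cc_label(fg)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = lab == largest
    mask = ndi.binary_closing(mask, structure=np.ones((5, 5)))
    # dark structures (hemorrhages, vessels) inside the eye fall below the
    # threshold; the disc itself is solid, so fill them back in
    return ndi.binary_fill_holes(mask)


def zero_background(img) -> FundusImage:
    """Set all pixels outside the detected eye disc to zero."""
    rgb = _as_rgb(img)
    mask = eye_disc_mask(rgb)
    if mask is None:
        warnings.warn("no above-threshold eye region found; image returned "
                      "unchanged", stacklevel=2)
        return FundusImage(pixels=rgb.copy())
    out = rgb.copy()
    out[~mask] = 0
    return FundusImage(pixels=out)


def green_channel(img) -> np.ndarray:
    """Extract the G plane of an RGB image."""
    return _as_rgb(img)[:, :, 1].copy()


def clahe(img: np.ndarray, clip_limit: float = DEFAULT_CLIP,
          tiles: int = CLAHE_TILES, nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a tiles x tiles
    grid.

    Classic formulation: each tile's histogram is clipped at
    ``clip_limit`` times the uniform bin height (which bounds the local
    contrast amplification by about that factor), the clipped excess is
    redistributed evenly, the per-tile equalization maps come from the
    clipped CDFs, and pixels are bilinearly interpolated between the four
    surrounding tile maps to avoid block seams.
    """
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("clahe expects a single-channel image")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    h, w = arr.shape
    if h < tiles or w < tiles:
        raise ValueError(f"image {arr.shape} smaller than the {tiles}x{tiles} "
                         "tile grid")
    arr = arr.astype(np.uint8)

    ys = np.linspace(0, h, tiles + 1).astype(int)
    xs = np.linspace(0, w, tiles + 1).astype(int)
    maps = np.empty((tiles, tiles, nbins), dtype=np.float64)
    for i in range(tiles):
        for j in range(tiles):
            block = arr[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            npix = block.size
            hist = np.bincount(block.ravel(), minlength=nbins).astype(np.float64)
            clip = max(clip_limit * npix / nbins, 1.0)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / nbins
            cdf = np.cumsum(hist)
            maps[i, j] = cdf / npix * (nbins - 1)

    # bilinear interpolation between the maps of the four nearest tiles
    cy = (ys[:-1] + ys[1:] - 1) / 2.0
    cx = (xs[:-1] + xs[1:] - 1) / 2.0

    def _axis(coords, centers):
        hi = np.clip(np.searchsorted(centers, coords), 0, len(centers) - 1)
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        span = centers[hi] - centers[lo]
        wgt = np.where(span > 0, (coords - centers[lo]) / np.where(span == 0, 1, span), 0.0)
        return lo, hi, np.clip(wgt, 0.0, 1.0)

    iy0, iy1, wy = _axis(np.arange(h), cy)
    ix0, ix1, wx = _axis(np.arange(w), cx)
    v = arr
    top = (maps[iy0[:, None], ix0[None, :], v] * (1 - wx)[None, :]
           + maps[iy0[:, None], ix1[None, :], v] * wx[None, :])
    bot = (maps[iy1[:, None], ix0[None, :], v] * (1 - wx)[None, :]
           + maps[iy1[:, None], ix1[None, :], v] * wx[None, :])
    out = top * (1 - wy)[:, None] + bot * wy[:, None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def gamma_correct(img: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """out = 255 * (in/255) ** gamma, rounded to 8 bit. Monotone; gamma < 1
    brightens (never decreases a normalized value)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    arr = np.asarray(img, dtype=np.float64)
    out = 255.0 * (arr / 255.0) ** gamma
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def enhance(img, clip_limit: float = DEFAULT_CLIP,
            gamma: float = DEFAULT_GAMMA) -> EnhancedImage:
    """Full chain: zero_background -> green_channel -> clahe -> gamma."""
    zeroed = zero_background(img)
    disc = (zeroed.pixels.sum(axis=2) > 0)
    g = green_channel(zeroed)
    eq = clahe(g, clip_limit=clip_limit)
    # CLAHE can lift zero-level margins; the background stays zeroed
    eq[~disc] = 0
    out = gamma_correct(eq, gamma=gamma)
    steps = [
        {"step": "background_zeroed"},
        {"step": "green"},
        {"step": "clahe", "tile": f"{CLAHE_TILES}x{CLAHE_TILES}",
         "clip": clip_limit},
        {"step": "gamma", "gamma": gamma},
    ]
    return EnhancedImage(pixels=out, steps=steps)
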