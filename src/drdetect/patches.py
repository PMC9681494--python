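"""Overlapping square patch extraction, augmentation, and probability-map
reconstruction.

Images are tiled with anchors at stride steps plus a final anchor at
``H - n`` (and ``W - n``) so coverage is complete without padding.
Patch predictions are merged back by averaging overlapping contributions
(max is available as an alternative), so the tile -> reconstruct round
trip is the identity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi


@dataclasses.dataclass
class PatchSet:
    patches: list               # list of n x n arrays
    placements: list            # list of (row_offset, col_offset)
    n: int
    stride: int
    source_shape: tuple         # (H, W)


def anchors(length: int, n: int, stride: int) -> list[int]:
    """Anchor offsets along one axis: stride steps plus a final anchor at
    ``length - n`` (deduplicated)."""
    if n > length:
        raise ValueError(f"patch size {n} exceeds image extent {length}")
    if not 1 <= stride <= n:
        raise ValueError("stride must be in [1, n]")
    pos = list(range(0, length - n + 1, stride))
    if pos[-1] != length - n:
        pos.append(length - n)
    return pos


def tile(img: np.ndarray, n: int, stride: int | None = None) -> PatchSet:
    """Tile a 2-D array into overlapping n x n patches (default 50% overlap)."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    stride = stride or n // 2
    rows = anchors(h, n, stride)
    cols = anchors(w, n, stride)
    patches, placements = [], []
    for r in rows:
        for c in cols:
            patches.append(img[r:r + n, c:c + n])
            placements.append((r, c))
    return PatchSet(patches=patches, placements=placements, n=n,
                    stride=stride, source_shape=(h, w))


def augment(image_patch: np.ndarray, mask_patch: np.ndarray,
            rng: np.random.Generator, max_angle: float = 360.0):
    """Apply one random spatial transform — horizontal/vertical flip and a
    rotation by a random angle — identically to an image patch and its
    ground-truth mask patch.

    Rotation corner voids are filled by reflection on the image; the mask
    is rotated nearest-neighbor and re-binarized so it stays binary.
    """
    if image_patch.shape != mask_patch.shape:
        raise ValueError("image and mask patch shapes differ")
    img, msk = image_patch, mask_patch
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:
        img, msk = img[::-1, :], msk[::-1, :]
    angle = rng.uniform(0, max_angle)
    img = ndi.rotate(img.astype(np.float64), angle, reshape=False,
                     order=1, mode="reflect")
    img = np.clip(np.rint(img), 0, 255).astype(image_patch.dtype)
    msk = ndi.rotate(msk, angle, reshape=False, order=0, mode="constant",
                     cval=0)
    msk = (msk > (msk.max() / 2 if msk.max() > 1 else 0)).astype(mask_patch.dtype)
    if mask_patch.max() > 1:
        msk = msk * mask_patch.max()
    return img, msk


def reconstruct(patch_maps, placements, height: int, width: int,
                merge: str = "mean") -> np.ndarray:
    """Merge per-patch probability maps into a full-resolution map.

    Pixels covered by k patches receive the arithmetic mean (or max) of
    the k predictions. Raises if any pixel is uncovered.
    """
    if merge not in ("mean", "max"):
        raise ValueError("merge must be 'mean' or 'max'")
    acc = np.zeros((height, width), dtype=np.float64)
    cnt = np.zeros((height, width), dtype=np.int64)
    if merge == "max":
        acc[:] = -np.inf
    for pm, (r, c) in zip(patch_maps, placements):
        pm = np.asarray(pm, dtype=np.float64)
        n0, n1 = pm.shape
        if r < 0 or c < 0 or r + n0 > height or c + n1 > width:
            raise ValueError(f"placement ({r}, {c}) outside {height}x{width}")
        if merge == "mean":
            acc[r:r + n0, c:c + n1] += pm
        else:
            np.maximum(acc[r:r + n0, c:c + n1], pm,
                       out=acc[r:r + n0, c:c + n1])
        cnt[r:r + n0, c:c + n1] += 1
    if (cnt == 0).any():
        raise ValueError("patch placements leave uncovered pixels")
    if merge == "mean":
        return acc / cnt
    return acc
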