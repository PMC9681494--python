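"""Synthetic fundus images with known lesion content.

Emulates the structure of public DR segmentation datasets: a circular eye
region on black margins, three lesion classes rendered as blobs with
class-specific size and intensity, a paired binary ground-truth mask per
class, and all-black masks for healthy images. Ground-truth lesion counts
are exactly recoverable by connected-component labeling of the emitted
masks, which makes the generator the oracle for the counting stage.

Intensity model (green channel, where lesion contrast is strongest):
exudates are the brightest structures (lipid deposits, ~215), the fundus
disc sits near 115 with a per-image illumination offset, microaneurysms
are small dark-red dots (~65) and hemorrhages the darkest, largest blobs
(~35). No public per-pixel statistics exist for these lesions, so the
levels are stand-ins chosen to preserve the qualitative ordering seen in
fundus photographs, not a calibration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import label as cc_label

from .io import save_image

LESION_CLASSES = ("MA", "EX", "HEM")

# (R, G, B) levels for the rendered structures
_DISC_RGB = np.array([185.0, 115.0, 40.0])
_LESION_RGB = {
    "MA": np.array([120.0, 65.0, 30.0]),    # small dark-red dots
    "EX": np.array([235.0, 215.0, 120.0]),  # bright yellowish deposits
    "HEM": np.array([70.0, 35.0, 25.0]),    # dark irregular bleeds
}


class PackingError(RuntimeError):
    """Raised when the requested blobs cannot be placed in the eye disc."""


@dataclasses.dataclass
class SynthSpec:
    """Parameters of one synthetic fundus image.

    Defaults are the desk-scale study conditions used throughout the test
    and evaluation harness: 96x96 images, eye disc at 46% of the image
    size, and blob radii small enough that several lesions of each class
    pack into the disc with a 2 px inter-blob gap.
    """

    image_height: int = 96
    image_width: int = 96
    eye_radius_fraction: float = 0.46
    lesion_counts: dict = dataclasses.field(
        default_factory=lambda: {"MA": 0, "EX": 0, "HEM": 0})
    blob_radius_range: dict = dataclasses.field(
        default_factory=lambda: {"MA": (2, 4), "EX": (4, 7), "HEM": (5, 8)})
    background_noise_sd: float = 6.0
    illumination_jitter: float = 12.0
    min_gap: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.eye_radius_fraction <= 1:
            raise ValueError("eye_radius_fraction must be in (0, 1]")
        largest = max(hi for _, hi in self.blob_radius_range.values())
        if min(self.image_height, self.image_width) < 4 * largest:
            raise ValueError("image dimensions must be >= 2x the largest "
                             "blob diameter")
        for cls in LESION_CLASSES:
            if self.lesion_counts.get(cls, 0) < 0:
                raise ValueError("lesion counts must be non-negative")


@dataclasses.dataclass
class FundusImage:
    pixels: np.ndarray            # H x W x 3 uint8
    source: str = ""
    severity: int | None = None


def _disc_mask(h: int, w: int, frac: float) -> tuple[np.ndarray, tuple, float]:
    center = (h / 2.0, w / 2.0)
    radius = frac * min(h, w)
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_disk(center, radius, shape=(h, w))
    mask[rr, cc] = True
    return mask, center, radius


def _place_blobs(rng, spec: SynthSpec, center, radius, placed):
    """Rejection-sample blob centers inside the disc, disjoint across all
    classes with a minimum gap so contour counting is unambiguous."""
    out = {}
    for cls in LESION_CLASSES:
        count = spec.lesion_counts.get(cls, 0)
        lo, hi = spec.blob_radius_range[cls]
        blobs = []
        for _ in range(count):
            for _attempt in range(200):
                r = rng.uniform(lo, hi)
                # keep the whole blob inside the disc
                rho = rng.uniform(0, max(radius - r - 2, 1))
                theta = rng.uniform(0, 2 * np.pi)
                cy = center[0] + rho * np.sin(theta)
                cx = center[1] + rho * np.cos(theta)
                ok = all(np.hypot(cy - py, cx - px) >= r + pr + spec.min_gap
                         for py, px, pr in placed)
                if ok:
                    placed.append((cy, cx, r))
                    blobs.append((cy, cx, r))
                    break
            else:
                raise PackingError(
                    f"could not place {count} {cls} blobs of radius "
                    f"{lo}-{hi} in a disc of radius {radius:.0f}")
        out[cls] = blobs
    return out


def _render_blob(mask, cls, cy, cx, r, rng):
    h, w = mask.shape
    if cls == "HEM":
        # union of 2-4 overlapping ellipses: larger, more irregular shape,
        # still ONE lesion (one connected mask component)
        n_parts = rng.integers(2, 5)
        a0 = r
        b0 = rng.uniform(0.6, 0.9) * r
        rr, cc = draw_ellipse(cy, cx, a0, b0, shape=(h, w),
                              rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True
        for _ in range(n_parts - 1):
            off = rng.uniform(0, 0.4 * b0, size=2) * rng.choice([-1, 1], 2)
            rr, cc = draw_ellipse(cy + off[0], cx + off[1],
                                  0.7 * a0, 0.7 * b0, shape=(h, w),
                                  rotation=rng.uniform(0, np.pi))
            mask[rr, cc] = True
    else:
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        mask[rr, cc] = True


def generate_image(spec: SynthSpec):
    """Render one image.

    Returns ``(FundusImage, {class -> uint8 mask in {0, 255}}, label)``
    with ``label`` "DR" iff any lesion was requested. Identical spec and
    seed give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_height, spec.image_width
    disc, center, radius = _disc_mask(h, w, spec.eye_radius_fraction)

    img = np.zeros((h, w, 3), dtype=np.float64)
    illum = rng.uniform(-spec.illumination_jitter, spec.illumination_jitter)
    img[disc] = _DISC_RGB + illum

    placed: list = []
    blobs = _place_blobs(rng, spec, center, radius, placed)

    masks = {}
    for cls in LESION_CLASSES:
        m = np.zeros((h, w), dtype=bool)
        for cy, cx, r in blobs[cls]:
            before = m.copy()
            _render_blob(m, cls, cy, cx, r, rng)
            img[m & ~before] = _LESION_RGB[cls] + illum * 0.5
        masks[cls] = (m.astype(np.uint8)) * 255

    noise = rng.normal(0, spec.background_noise_sd, size=(h, w, 3))
    img[disc] += noise[disc]
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    total = sum(spec.lesion_counts.get(c, 0) for c in LESION_CLASSES)
    label = "DR" if total > 0 else "healthy"
    return FundusImage(pixels=pixels), masks, label


def true_counts(masks: dict) -> dict:
    """Connected-component oracle: exact lesion count per class mask."""
    return {cls: int(cc_label(masks[cls] > 0).max())
            for cls in LESION_CLASSES}


def _severity_from_counts(counts: dict) -> int:
    total = sum(counts.values())
    if total == 0:
        return 0
    # more lesions -> higher grade, capped at proliferative (4)
    return int(min(4, 1 + (total - 1) // 3))


def generate_dataset(n_healthy: int, n_dr: int, out_dir,
                     template: SynthSpec | None = None, seed: int = 0,
                     max_counts: dict | None = None) -> pd.DataFrame:
    """Write a labeled image/mask dataset and return its manifest.

    DR rows draw per-class lesion counts uniformly from 0..max (at least
    one lesion in total); healthy rows get all-black masks. The manifest
    CSV has columns ``image,ma_mask,ex_mask,hem_mask,label,severity``.
    """
    if n_healthy < 0 or n_dr < 0:
        raise ValueError("counts must be non-negative")
    template = template or SynthSpec()
    max_counts = max_counts or {"MA": 4, "EX": 3, "HEM": 2}
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    rows = []
    labels = ["healthy"] * n_healthy + ["DR"] * n_dr
    for i, want in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        if want == "healthy":
            counts = {c: 0 for c in LESION_CLASSES}
        else:
            while True:
                counts = {c: int(rng.integers(0, max_counts[c] + 1))
                          for c in LESION_CLASSES}
                if sum(counts.values()) > 0:
                    break
        spec = dataclasses.replace(
            template, lesion_counts=counts,
            rng_seed=int(rng.integers(0, 2**31 - 1)))
        image, masks, label = generate_image(spec)
        stem = f"{label.lower()}_{i:04d}"
        img_path = out_dir / "images" / f"{stem}.png"
        save_image(img_path, image.pixels)
        mask_paths = {}
        for cls in LESION_CLASSES:
            p = out_dir / "masks" / f"{stem}_{cls.lower()}.png"
            save_image(p, masks[cls])
            mask_paths[cls] = p
        rows.append({
            "image": str(img_path),
            "ma_mask": str(mask_paths["MA"]),
            "ex_mask": str(mask_paths["EX"]),
            "hem_mask": str(mask_paths["HEM"]),
            "label": label,
            "severity": _severity_from_counts(counts),
        })
    manifest = pd.DataFrame(rows, columns=["image", "ma_mask", "ex_mask",
                                           "hem_mask", "label", "severity"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image", "ma_mask", "ex_mask", "hem_mask", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    for col in ("image", "ma_mask", "ex_mask", "hem_mask"):
        for p in df[col]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
    return df
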