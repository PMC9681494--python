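# Methods

`drdetect` implements a two-branch pipeline for binary diabetic-retinopathy
(DR) detection from color fundus photographs, exercisable end to end on
synthetic images with known ground truth.

## Pipeline

1. **Contrast enhancement.** Non-eye margins are zeroed (Otsu threshold on
   grayscale, largest connected component, 5×5 morphological closing, hole
   filling so dark structures inside the eye are kept). The green channel is
   extracted — it carries the strongest lesion/vessel contrast — then
   contrast-limited adaptive histogram equalization (CLAHE) on an 8×8 tile
   grid, then gamma correction `out = 255·(in/255)^γ` with γ = 0.8
   (a brightening, monotone map).
2. **Patch-based segmentation.** The enhanced image and each per-lesion
   binary mask are cut into overlapping n×n patches (anchors at stride
   steps plus a final anchor at `H−n`/`W−n`, so no padding is invented).
   One U-Net per lesion class — microaneurysms (MA), exudates (EX),
   hemorrhages (HEM) — is trained with binary focal loss under 5-fold
   cross-validation, 3 epochs per fold, batch 32, steps per epoch = patches
   / batch. Patch probability maps are merged back at full resolution by
   averaging overlapping predictions and thresholded at 0.5.
3. **Lesion counting.** The lesion count of a binary mask is the number of
   distinct closed object contours: Canny edges around foreground regions,
   morphological closing to bridge edge gaps, hole filling to close the
   shapes, then object counting (snapped back onto the mask so an edge
   bridge across the gap between two nearby lesions cannot merge them). On
   masks whose components are ≥ 2 px apart this equals connected-component
   labeling exactly; the suite asserts that equivalence on 210 generator
   masks. Canny cannot resolve a 1×1-px object; the generator never emits
   blobs below 2 px radius.
4. **Deep features.** Topless VGG-16 and ResNet-50 backbones (classifier
   heads removed) map a bilinearly resized, ImageNet-normalized 224×224×3
   input to their terminal convolutional volumes — 7×7×512 and 7×7×2048 —
   flattened row-major over (row, col, channel) into 25,088- and
   100,352-dim vectors. Pretrained weights require a download, so the
   default weight source is a seeded He initialization: every dimension
   contract is architecture-level and weight-independent, and random-weight
   features double as the uninformative baseline in the ablation.
5. **Fusion and classification.** Feature blocks are concatenated in the
   fixed order `[deep ‖ MA ‖ EX ‖ HEM]` (25,091 or 100,355 dims with both
   blocks). An XGBoost classifier with library defaults and a fixed seed
   is trained per feature subset; the ablation harness covers every
   non-empty block combination plus each lesion count alone. Reported
   metrics: accuracy (as percent), precision, recall, F1, and ROC AUC
   (trapezoidal; equals the midrank Mann–Whitney statistic, which the
   suite checks by brute-force pairwise counting).

## Neural-network engine

No deep-learning framework is part of the dependency set; the models run
on a compact numpy engine (`drdetect.nn`): im2col convolutions contracted
via BLAS, manual backprop, Adam. The U-Net has five convolution levels
(two 3×3 same-padding conv+ReLU per level, 2×2 max-pool between encoder
levels, 2×2 transpose-conv upsampling with skip concatenation, 1×1 sigmoid
head); filter widths double per level from `base_filters`, so the patch
size must be divisible by 16. The backbones are forward-only.

Two initialization choices matter at small scale: inputs are centered to
[−1, 1] (He initialization assumes zero-mean inputs; uncentered [0, 1]
patches measurably slow convergence), and the output bias starts at −2 so
the network begins near the background-dominated prior instead of spending
its first updates suppressing foreground probability everywhere.

## Focal loss

Per pixel, with prediction p ∈ (0,1) clamped by ε = 1e−7:

    y = 1:  α · (1−p)^γ · (−log p)
    y = 0:  (1−α) · p^γ · (−log(1−p))

averaged over all pixels. Defaults γ = 2.0, α = 0.25 (the canonical
parameterization); γ = 0, α = 0.5 reduces it to half the standard binary
cross-entropy. Lesion masks are foreground-sparse (≈ 2% of pixels at desk
scale), which is why a plain cross-entropy tends to collapse to the
background class.

## Synthetic study conditions

The generator emulates the *structure* of public DR segmentation datasets,
not their appearance: a circular eye disc on black margins, three lesion
classes as blobs with class-specific size and intensity, paired binary
masks ({0,255}), all-black masks for healthy images, and a CSV manifest.
Blob centers are rejection-sampled inside the disc with a ≥ 2 px
inter-blob gap (making count recovery by labeling exact); a hemorrhage is
a union of 2–4 overlapping ellipses — larger and more irregular than the
other classes — but still one lesion. In the green channel, exudates are
the brightest structures (~215), the disc sits near 115 with a per-image
illumination offset (±12, so global brightness does not leak the label),
microaneurysms are small dark dots (~65), hemorrhages the darkest blobs
(~35), with Gaussian noise (sd 6) over the disc. No public per-pixel
lesion statistics exist, so these levels are stand-ins that preserve the
qualitative ordering seen in fundus photographs — passing tests show the
pipeline recovers *separable* lesions exactly, not that it matches
clinical segmentation accuracy on real images, which also contain
vasculature, optic disc, and camera artifacts the generator deliberately
omits.

Desk-scale defaults, chosen once for the evaluation harness: 96×96 images,
eye radius fraction 0.46, DR images draw per-class counts uniformly from
0–4 (MA), 0–3 (EX), 0–2 (HEM) with at least one lesion; the DR label is
exactly "any lesion present". Segmentation uses 32-px patches at stride 8
(81 overlapping patches per image), 8 base filters, learning rate 1e−2 —
with 40 images this yields 81 gradient steps per epoch, which the fixed
3-epoch protocol needs to converge; at full scale the documented defaults
are the per-lesion patch sizes 128 (MA) and 256 (EX/HEM), 16 base filters
and learning rate 1e−3. Individual folds can still collapse at this scale
(12–243 steps is a thin budget); the protocol retains the best-accuracy
fold per class, and measured best-fold validation IoU is ≈ 0.66–0.92
depending on class, hemorrhages being hardest (irregular shape, darkest
band adjacent to the microaneurysm band).

## Numerical choices

- CLAHE is the classic formulation: per-tile histograms clipped at
  `clip_limit` × the uniform bin height (default 2.0, bounding local
  contrast amplification by about that factor), excess redistributed
  evenly, per-tile maps bilinearly interpolated. Normalized-clip variants
  degenerate on very small tiles (the clip floors out and noise is
  amplified to the full range), which is visible at 96-px desk scale.
- Probability→mask threshold is 0.5; merge rule for overlapping patch
  predictions is the arithmetic mean (max available).
- Augmentation (random horizontal/vertical flip plus rotation by a random
  angle) applies the identical spatial transform to image and mask;
  rotation corner voids are reflection-filled on the image, and the mask
  is rotated nearest-neighbor and re-binarized. Each training patch is
  augmented with probability 0.5.
- Zero-denominator metrics (recall with no true foreground, F1 with
  P+R = 0, AUC on a single-class test set) are reported as explicit
  `None`, never silently 0.
- Determinism: every stochastic stage (generator, fold shuffling,
  augmentation, weight init, XGBoost) derives its seed from the caller's
  seed; identical configuration reproduces identical artifacts.

## Known limitations

- The detection classifier keeps the boosting library's default
  hyperparameters (the protocol this package follows trains it that way).
  At desk-scale sample sizes this has a measurable calibration artifact:
  `min_child_weight = 1` refuses splits whose child hessian is below 1,
  so a count pattern represented by a single training image (e.g. one DR
  image whose only lesion is a lone hemorrhage) can be left in a leaf
  dominated by healthy images and scored just below the 0.5 decision
  threshold — even when the count features rank the classes perfectly
  (AUC 1.0). The effect disappears as the training set grows (with
  ground-truth counts it affects some 40-image draws, few 80-image draws,
  and none observed at 120); it is a property of the pinned classifier
  protocol at small n, not of the lesion features.
- Random-weight backbone features are an architecture-level stand-in:
  they validate dimensions, plumbing, and the feature-ablation mechanics,
  but they are not guaranteed to be uninformative on synthetic images —
  bright/dark blobs on a uniform disc are visible to random convolutional
  projections too, so the deep-only ablation arm can score well above
  chance on this generator (unlike real fundus texture, where lesion
  evidence is subtle). Conclusions about the relative worth of deep vs
  lesion features on real data require pretrained weights and real
  images.
- The per-fold step budget at desk scale makes individual folds
  seed-sensitive; only the retained (best) fold is guaranteed useful.
- Lesion counting is count-only by design; no per-lesion matching between
  prediction and truth, and no area/shape descriptors.
- The CLI's `--tile` option is fixed at 8 (the tile grid is part of the
  method); only clip limit and gamma are tunable.
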