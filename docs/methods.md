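# Methods

## Problem and approach

Hairline fractures of the pediatric distal humerus are hard to read because
the normal skeleton provides its own confounders: ossification centres and
the epiphyseal line produce bright, line-like structures, while the
fracture itself is a faint lucent line crossing the cortex. Labeled
fracture images are scarce; healthy radiographs are plentiful. The pipeline
therefore learns *normality*: an inpainting model trained exclusively on
healthy crops reconstructs an occluded central region, and deviations of
the input from its healthy reconstruction (`Diff = |I − R|`) flag
anomalies. A supervised patch-grid head then turns crop + reconstruction +
residual into per-cell fracture probabilities.

## Phantom generator

Real data is not distributable, so `mprfrax.phantoms` draws seeded
parametric phantoms that reproduce the *statistical structure* that makes
the problem hard, not anatomy:

- soft-tissue background 0.22, bone shaft interior 0.52 with slight tilt
  and curvature, bone width 0.30–0.42 of the image;
- bright cortical margins (+0.30, ~4.5% of the image wide) — the strong
  normal edges;
- an epiphyseal-line-like Gaussian band (+0.12) at a random height in the
  lower shaft, and 0–2 ossification-centre blobs (+0.14) — the fracture
  mimics;
- additive Gaussian noise, σ = 0.02;
- positives: an anti-aliased lucent crack (default depth 0.15, thickness
  1 px, length 14 px) crossing a cortical margin near the image centre,
  annotated with the tight modified-pixel box dilated by 2 px.

All outputs are pure functions of `(spec, seed)`. Coordinates are 0-based,
half-open, `(row, col)` everywhere. Deliberate limitations: no projection
physics, no scatter/heel effects, no patient variation in pose, no joint —
so green tests here demonstrate the *mechanism* (normality learning,
residual contrast, weighted-grid localization), not clinical performance.

## Scales

The full-scale geometry is 256×256 crops with a centred 160×160 mask in a
5×5 grid of 32×32 sub-regions, and the published training recipe (Adam,
lr 1e-4 decayed 5% every 5 epochs, batch 8, dropout 0.5, ≤100 epochs,
early stopping). The desk scale divides the geometry by 4 (64×64 crops,
40×40 mask, 8×8 sub-regions), narrows every network, raises the learning
rates (repair 1e-3, detector 2e-3 — small nets, few steps), and trains in
minutes on one CPU: 200 healthy phantoms / 30 epochs for repair, 200
labeled phantoms / 20 epochs for detection, evaluated on a disjoint
100+100 set. The 9×9 label grid tiles any crop size (base cell
`size // 9`; the last row/column absorb the remainder — 28 px cells with a
32 px last cell at 256).

## Repair model

Encoder–decoder with strided-conv downsampling, nearest-neighbour-upsample
decoding and skip connections at two scales; a three-stride patch
discriminator; losses

- adversarial: non-saturating GAN cross-entropy on patch logits;
- perceptual: element-normalized squared activation differences of a small
  *frozen, seeded* random conv feature net (at full scale a pretrained
  VGG-style provider can be plugged in — random conv features preserve
  enough geometry to serve as a perceptual metric at desk scale);
- region: mean absolute error inside the occluded region;

combined as `α·adv + β·perc + γ·region` with defaults (0.1, 1.0, 1.0) —
the weights are not published, so they are config with mandatory logging.
The sub-region fill defaults to the training set's mean intensity per
sub-region slot.

**Occlusion strategy.** Whether the 25 sub-regions are repaired jointly or
one at a time is genuinely open. We measured both and use a guarded
per-region sweep at desk scale: each pass occludes the 3×3 block of
sub-regions around a target region and keeps only the target's
reconstruction (training occludes the same guarded blocks, one random
target per sample). Joint masking forces the generator to hallucinate the
whole central area — the randomly placed band/blobs are then unpredictable
and healthy residuals grow as large as crack residuals; a naive one-region
sweep leaks the crack, which remains visible just outside the 8×8 hole and
is simply continued into it. The 1-ring guard (24×24 occlusion at desk
scale) hides any crack centred in the target while keeping distant anatomy
visible. Compositing (pasting original pixels outside the mask) is on by
default, so residuals are exactly zero outside the repaired area.

## Detector

ConvNeXt-style blocks (depthwise 7×7, 4× pointwise expansion, layer
scale) in three stages, FPN top-down fusion, per-level projection onto the
9×9 grid, concatenation, 1×1 head. Desk-specific choices, each motivated
by the hairline regime at 64 px:

- stem stride 2 (not 4): a stride-4 patchify stem averages a 1 px crack
  away before any feature extraction;
- resizing FPN maps onto the grid uses exact area-overlap pooling rather
  than 2-tap bilinear sampling, so every pixel's evidence reaches its cell;
- input channels: crop, composited reconstruction, residual. Giving the
  head the reconstruction (not only `|I − R|`) lets it compare the two
  images shift-tolerantly; one-pixel edge misalignments dominate the raw
  residual and were the main false-positive source;
- label-consistent augmentation (horizontal/vertical flips mirroring the
  label grid, brightness jitter ±0.05 on the intensity channels, extra
  noise σ 0.01 on the crop) — the source recipe also augments heavily;
- exponential moving average of the weights (decay 0.98); the averaged
  model is validated and returned, which substantially reduces seed-to-seed
  variance at 20-epoch budgets.

**Loss.** Cells are positive when their overlap fraction
`|cell ∩ bbox ∩ repair-mask| / |cell|` is nonzero (fractions are kept for
analysis; the binarization threshold is configurable). The weighted BCE
uses the per-image non-fracture fraction ρ. On an all-healthy image ρ = 1
and the negative-class weight (1−ρ) vanishes — such images would carry no
gradient at all, which empirically collapses specificity to zero. Training
therefore substitutes the dataset-level ρ for grids with no positive cell;
`wbce_loss` keeps the pure per-image formula and takes ρ as an explicit
optional argument.

**Decision rule.** Image score = max cell probability. Because the W-BCE
weighting intentionally inflates probabilities (a cell with a ~10% fracture
posterior is pushed toward ~0.5), the natural operating point of this score
is far above 0.5. The pipeline calibrates the threshold on a dedicated
healthy calibration cohort (default 100 freshly generated phantoms, seen by
neither model), never on test data, using a screening-style rule: the
threshold is the `spec_target` (default 0.90) quantile of the cohort's
scores, so the expected specificity equals the target. Using only the
healthy score distribution, estimated on a cohort of this size, proved far
more stable than Youden's J on the ~30-image validation split, where two or
three outliers on either side drag the optimum to an extreme.
`image_decision` itself defaults to 0.5 for standalone use.

## Evaluation

Sensitivity, specificity, accuracy and F1 from exact confusion counts
(undefined ratios reported as missing, not zero); ROC/AUC via the rank
method; SSIM/PSNR from scikit-image; and an embedder-qualified Fréchet
distance `‖μ_a−μ_b‖² + Tr(Σ_a+Σ_b−2(Σ_aΣ_b)^{1/2})` with ε·I
regularization of the matrix square root (ε = 1e-6). True FID requires
pretrained Inception weights; the desk embedder is a seeded random conv
net, and values are only comparable between runs using the same embedder.

## Numerical choices and degenerate inputs

- Fourier high-pass: the transfer function is pluggable (Gaussian default,
  ideal hard cutoff available); the DC-centred distance matrix uses
  `d = hypot(u − M//2, v − N//2)`; magnitude is kept after the inverse
  transform and min-max normalized per image. A constant image yields an
  identically ~zero map before normalization and a zero map after.
- Bicubic ROI resampling clamps to [0,1] afterwards (cubic overshoot); a
  crop already at the target size is returned verbatim; boxes are clipped
  to the image and must be nonempty after clipping.
- W-BCE probabilities are clipped to [1e-7, 1−1e-7].
- Crack placement that falls outside the bone raises a placement error;
  amplitude 0 is the exact identity.
- All training is float32 on a hand-written NumPy conv-net engine whose
  layer gradients are verified against finite differences in the test
  suite; runs are bit-reproducible for a fixed seed on a given platform.

## Known limitations

- Phantoms are low-fidelity by design; absolute metric values do not
  transfer to hospital data.
- The ROI fallback assumes the bone dominates the intensity-weighted
  foreground; rotated or off-centre anatomy needs a real detector plug-in.
- Anisotropic scaling is accepted when a plugged-in detector returns a
  non-square box (the box is resized as given).
- The desk perceptual loss uses random features; it regularizes but does
  not match a pretrained perceptual metric.
- Fréchet distances from the desk embedder are not FID-comparable.
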