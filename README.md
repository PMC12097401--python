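# mprfrax

Reconstruction-based detection and localization of **subtle (hairline)
fractures on elbow radiographs**, aimed at the pediatric supracondylar
region where ossification centres and epiphyseal lines mimic fracture lines
and labeled fracture data is scarce.

The package implements a multi-scale patch-residual pipeline:

1. **ROI localization** — the elbow region is cropped to a standardized
   square input (pluggable detector; deterministic intensity-centroid
   fallback).
2. **Auxiliary channels** — a bone-edge map (Canny/Sobel or a small
   trainable multi-scale edge net) and a high-frequency texture map,
   `H(u,v) = 1 − exp(−d²/2λ²)` applied in the 2-D Fourier domain (λ = 10).
3. **Healthy-bone inpainting** — a masked adversarial encoder–decoder
   (generator `M_E`/`M_D`, patch discriminator `D_f`) is trained **only on
   healthy images** to restore a centred occluded region (160×160 of a
   256×256 crop, tiled into 5×5 solid-fill sub-regions), supervised by

   `L_G = α·L_adv + β·L_perc + γ·L_region`,

   so the model learns the distribution of normal bone. For an input `I`
   with reconstruction `R`, the residual `Diff = |I − R|` is near zero for
   normal anatomy and elevated at fractures.
4. **Patch-grid detection** — crop, reconstruction and residual are fed to
   a ConvNeXt-style backbone with an FPN head that emits a 9×9 grid of
   fracture probabilities, trained with weighted binary cross-entropy

   `L = −(1/81) Σ_ij [ρ·y·log p + (1−ρ)·(1−y)·log(1−p)]`,

   where ρ is the per-image fraction of non-fracture cells (~0.95), so the
   rare fracture cells are up-weighted by the imbalance itself.
5. **Decision + heatmap** — image score = max cell probability; the grid is
   rendered as a colormap overlay for reading-room style review.

Hospital radiographs are not distributable, so the `phantoms` module
generates seeded synthetic elbow-like radiographs (bright shaft with
cortical margins, epiphyseal-line-like band, ossification-centre blobs,
noise) with hairline cracks and exact bounding boxes; the whole pipeline is
trained and evaluated on these at desk scale (64×64 crops) on one CPU.
Everything trains on a small pure-NumPy conv-net engine with manual
backprop (`mprfrax._nn`) — no GPU or deep-learning framework required.

## Worked example

```python
from mprfrax import pipeline

manifest = pipeline.run_pipeline(pipeline.PipelineConfig(seed=1))
print(manifest["metrics"])
```

prints (one CPU, ≈7 minutes):

```
{'sensitivity': 0.96, 'specificity': 0.91, 'accuracy': 0.935,
 'f1': 0.9365853658536586, 'auc': 0.9835, 'n_test': 200,
 'localization_hit_rate': 1.0, 'n_detected_fractures': 96}
```

meaning: with the repair model trained on 200 healthy phantoms (30 epochs)
and the detector on 200 labeled phantoms (20 epochs), 96/100 fractured and
91/100 healthy phantoms of a disjoint test set are called correctly at the
threshold calibrated on a healthy cohort, and for every detected fracture
the hottest grid cell lies inside a truly fractured cell. Single images:

```python
dec, grid = pipeline.predict_one("xray.png", repair, detector, cfg,
                                 heatmap_path="overlay.png")
```

A CLI wraps the same stages: `mprfrax phantom | run | train-repair |
predict | evaluate` (see `mprfrax --help`).

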