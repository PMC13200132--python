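# orbitsharp

Quantitative image-quality and edge-sharpness analysis for paired grayscale
MRI slices — typically a conventionally reconstructed (CR) image and its
deep-learning reconstructed (DLR) counterpart — with synthetic orbital
phantoms as a ground-truth test bed.

Deep-learning reconstruction of accelerated MRI changes how anatomical
boundaries look: edges can become steeper and narrower while fine texture is
smoothed. Radiology studies usually report this only as subjective Likert
ratings. This package implements the quantitative counterpart: edge
extraction, edge-sharpness features, blur and perceptual-sharpness metrics,
reference similarity metrics, and the agreement statistics needed to compare
two reconstructions across a patient cohort and across edge detectors.

## What it computes

For a normalized image I with central-difference gradient (G_x, G_y) and
magnitude |∇I| = √(G_x² + G_y²):

* **Mean edge steepness** — for each edge pixel (Roberts, Sobel or Canny
  map), the maximum of |∇I| in a small neighborhood (default 3×3), averaged
  over edge pixels. Units: intensity/px.
* **Mean edge width** — the 10–90% rise distance of the intensity profile
  cast through each edge pixel along the local gradient direction
  (0.25-px sampling, sub-sample crossings). For a step edge blurred with a
  Gaussian of SD σ the true value is 2.5631 σ, which calibrates the
  estimator. Units: px.
* **Mean edge contrast** — max − min intensity in a local window around each
  edge pixel (default 7×7), on the normalized [0, 1] scale.
* **Reference metrics** — SSIM, MS-SSIM, SNR, PSNR, and a blur percentage
  (relative loss of mean gradient magnitude: 0% for an identical image,
  100% for a completely blurred one).
* **No-reference metrics** — a perceptual blur metric in [0, 1] (re-blur
  construction: how much neighbor-intensity variation survives a strong box
  filter) and a Perceptual Sharpness Index (PSI; top-percentile reciprocal
  edge widths over image blocks).
* **Statistics** — Wilcoxon signed-rank and paired t tests for CR vs DLR,
  Cohen's κ and Kendall's τ-b/τ-c for rater agreement, within-participant
  coefficient of variation, and two-way mixed-effects ICC (consistency and
  absolute agreement, single and average measures) for cross-detector
  agreement.

FSIM and WASH are not implemented; `orbitsharp.metrics.register_metric`
accepts external implementations under the same reporting schema.

## Worked example

```python
from orbitsharp import (generate_paired_study, run_study_on_pairs,
                        summarize_edge_features, ssim, psnr)

pairs = generate_paired_study(n_subjects=25, seed=7)
cr, dlr = pairs[0].cr, pairs[0].dlr
for label, img in (("CR-like", cr), ("DLR-like", dlr)):
    r = summarize_edge_features(img, "sobel")
    print(f"{label}: steepness={r.mean_steepness:.3f}  "
          f"width={r.mean_width_px:.2f} px  contrast={r.mean_contrast:.3f}")
print(f"SSIM(CR, DLR) = {ssim(cr, dlr):.3f}, PSNR = {psnr(cr, dlr):.2f} dB")
```

```
CR-like: steepness=0.141  width=5.00 px  contrast=0.552
DLR-like: steepness=0.180  width=2.76 px  contrast=0.512
SSIM(CR, DLR) = 0.518, PSNR = 29.12 dB
```

The DLR-like member (narrower edge blur, less noise, slightly reduced
contrast) shows higher steepness, roughly half the edge width and slightly
lower edge contrast — the expected signature of a sharpening reconstruction.
`run_study_on_pairs(pairs)` aggregates the full cohort: per-pair metrics,
mean ± SD summaries, paired tests (steepness CR 0.144 vs DLR 0.188,
Wilcoxon p ≈ 6e-8 at n = 25) and cross-detector CV/ICC tables.

The same analysis runs from the shell on a manifest CSV:

```sh
orbitsharp phantom --out data/ --n 25 --seed 7
orbitsharp study --manifest data/manifest.csv --out report/
```

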