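# Methods

## Scope and data model

All analysis operates on `GrayImage`: a 2D float array with finite
intensities, normalized per image to [0, 1] by min–max rescaling (optional
percentile clipping for heavy-tailed inputs). Per-image normalization is a
deliberate choice — acquisition scaling differs between reconstructions, and
normalizing each image makes steepness (intensity/px) and contrast
(intensity units) comparable across images; the normalization mode is
recorded in outputs. A constant image normalizes to zeros with a warning
flag rather than raising, so batch runs survive degenerate inputs. All
metric operations require at least 8×8 images.

Gradients are central differences in the interior and one-sided differences
on the border (the `numpy.gradient`/MATLAB `gradient` convention), so a
linear ramp has its exact slope at every pixel. The gradient magnitude
√(G_x²+G_y²) is rotation-invariant up to grid effects; the test suite checks
transpose invariance exactly and 30°-rotation stability of the derived
features to within 5%.

## Edge extraction

Roberts (2×2 diagonal kernels) and Sobel (3×3) magnitude maps are
thresholded and then thinned by non-maximum suppression along the
central-difference gradient direction (4-sector quantization, ties kept),
so "edge pixels" approximate one-pixel ridges; un-thinned maps are
available (`thin=False`). Canny is scikit-image's implementation (Gaussian
presmoothing, default σ = 1 px, NMS, hysteresis).

**Automatic thresholds.** The default is Otsu's split of the nonzero
gradient magnitudes, guarded from below by a noise floor of 4× the median
magnitude of the whole grid. Plain Otsu fails in a specific, reproducible
way on noisy images whose edge pixels are rare: the histogram is dominated
by the Rayleigh-distributed noise magnitudes and the split lands inside the
noise bulk (on the noisy CR-like phantom it marked 31% of all pixels as
Roberts edges). The median of the full grid estimates the noise scale — and
is exactly 0 on noise-free images with flat interiors, where the guard is
inert. For Canny the same guard must also clear the *low* hysteresis
threshold (low = 0.4 × high, the conventional ratio), otherwise edge
tracking floods through the above-low noise lattice; thresholds are
computed in the units of Canny's own magnitude (unnormalized Sobel of the
smoothed image) and logged. The outermost 1-px frame is excluded from all
edge maps: gradients there are one-sided and profile lines would leave the
image.

## Edge-sharpness features

**Steepness** is the maximum gradient magnitude in a window around each
edge pixel (default 3×3, clipped at borders), always measured on the
central-difference gradient of the image itself regardless of which
detector selected the pixel. It equals an exhaustive per-window search by
construction; the suite asserts exact agreement on random images.

**Width** is the 10–90% rise distance of an intensity profile through the
edge pixel along ± the unit gradient direction: half-length 5 px, 0.25-px
sampling, oriented low-to-high, with the level crossings located by linear
interpolation between samples and the crossing *nearest the profile center*
taken on each side so neighboring structures do not inflate the width.
Profiles are sampled with cubic spline interpolation. Bilinear sampling —
the more common default — interpolates the edge-spread function with
straight chords between 1-px nodes and systematically widens the apparent
10–90 rise of narrow edges: +6.3% at σ = 1 and +12% at σ = 0.75 (measured
against the closed form), while cubic stays within ~1% for σ ≥ 1. The
interpolation order is a parameter (`interp_order`; 1 recovers the bilinear
convention, under which an ideal discrete step measures exactly 0.8 px).
Profiles with total contrast below 0.05 (normalized units), without both
crossings, or leaving the image are excluded and counted
(`n_valid_widths`). The calibration identity width = 2.5631 σ for a
Gaussian-blurred step holds only when the profile spans the transition;
calibration runs use half-length ≥ 4σ + 2, and the 5-px default suits
σ ≲ 2.

**Contrast** is max − min intensity in a window around each edge pixel,
default 7×7. The window half-width must be at least half the widest 10–90
transition being measured: a window that clips the transition reports only
a fraction of the true edge contrast (79% at σ = 1.6 for a 5×5 window vs
97% at σ = 0.9), a bias that *grows with blur* and can therefore invert a
comparison between a blurry and a sharp reconstruction of the same anatomy.
The 7×7 default spans transitions up to σ ≈ 2.3 px; the window is a
parameter and is logged.

## Image-quality metrics

SSIM uses the standard construction: Gaussian-weighted local statistics
(11-tap window, σ = 1.5), K1 = 0.01, K2 = 0.03, dynamic range 1, population
covariance, border strip of the filter radius cropped. The test suite
checks the zero-variance closed form and exact agreement (≤ 1e-6) with an
independent implementation. MS-SSIM is the 5-scale weighted product
(weights 0.0448, 0.2856, 0.3001, 0.2363, 0.1333) of contrast-structure
terms with the full SSIM at the coarsest scale; images too small for five
dyadic scales use fewer with renormalized weights and a warning. PSNR and
reference SNR follow their dB definitions; identical images report the
infinity sentinel, serialized as "inf".

**Blur percentage** (reference): 100 · max(0, 1 − HF(test)/HF(ref)) with HF
the mean gradient magnitude, clamped to [0, 100]. This variant is chosen
because it satisfies both anchor semantics exactly — 0% for an identical
comparison image and 100% for a completely blurred (constant) one — and is
monotone in Gaussian blur; the variant name is recorded in outputs.

**Perceptual blur metric** (no-reference, 0 = sharpest): the image is
re-blurred with length-9 horizontal and vertical box filters; the total
absolute neighbor difference destroyed by re-blurring, relative to the
original total, gives one value per direction and the worse (larger) is
reported. A constant image is 1.0 by convention. This construction is
noise-sensitive by design of its mechanism: white noise is almost entirely
destroyed by the box filter and therefore reads as sharpness. See
"What the phantoms do and do not show" below.

**PSI** (no-reference): strong edges are located (Sobel map), their 10–90%
widths measured along the gradient normal (which needs no slope correction
for edge orientation), widths floored at 0.8 px (the narrowest measurable
step under the sampling scheme); local sharpness is the reciprocal width,
blocks of 32 px take their sharpest edge, and the index is the mean of the
top 22% of block values. The just-noticeable-blur width w_JNB = 3 px is a
parameter; with `clamp_jnb=True` widths below it are treated as maximally
sharp, capping the index at 1/3. The cap is off by default: reported PSI
values above 1/3 for sharp reconstructions, and the requirement that the
index decrease strictly with increasing blur (the property the suite
enforces), both need the unclamped reciprocal.

## Synthetic phantoms

A phantom is a piecewise-constant orbital scene — background 0.05, a globe
ellipse at 0.55, a lens ellipse at 0.85, an oblique optic-nerve bar at
0.70 on a 256×256 canvas — blurred by a Gaussian of SD `edge_sigma`, plus
additive white Gaussian noise (`noise_sd`), clipped to [0, 1]. Geometry is
analytic, so boundary ground truth is available for localization tests.
`contrast_scale` multiplies all region intensities, scaling every edge
contrast by the same factor.

The paired cohort emulates the CR/DLR contrast: CR-like members use
edge_sigma 1.6 px, noise SD 0.03, contrast scale 1.0; DLR-like members use
0.9 px, 0.012 and 0.95, with per-subject geometry jitter shared within a
pair. The defaults encode the expected direction of every effect —
steepness up, width down, contrast slightly down for DLR — so the cohort is
a known-answer benchmark for the whole pipeline. Cohort size defaults to
25 subjects, a typical single-center reading study. Generation is
bit-identical for a fixed seed.

**What the phantoms do and do not show.** The phantoms test the *metrics*,
not MR physics: noise is white Gaussian rather than Rician and spatially
uncorrelated, there is no k-space apodization, fat saturation, texture or
partial-volume structure, and most of the canvas is flat. Two consequences
are worth stating. First, flat interiors make the noise-floor behavior of
edge detectors easy to probe — which is why the threshold guard exists.
Second, the perceptual blur metric's noise sensitivity dominates on these
images: because the noise is white and the background flat, the noisier
CR-like member scores *lower* (sharper) than the DLR-like member at the
default cohort settings (≈0.16 vs ≈0.20), the opposite of its behavior on
real MRI where reconstruction band-limits the noise. Noise-free, the
ordering is as expected (≈0.76 vs ≈0.57 at those blur levels). Passing
cohort tests therefore validates the direction of steepness, width,
contrast and PSI effects; the perceptual blur metric's cohort direction is
a known limitation of white-noise phantoms, not of the metric
implementation, and is left failing in the acceptance suite rather than
patched around.

## Statistics

Wilcoxon signed-rank drops zero differences (classic convention; all-zero
input returns p = 1 with a warning) and uses the exact null for small
tie-free samples, otherwise the tie-corrected normal approximation. The
paired t-test reports a signed infinite t with p = 0 for constant nonzero
differences. Cohen's κ is unweighted; κ is undefined (NaN sentinel) when
both raters use a single shared category. Kendall's τ-b/τ-c use the
standard tie corrections. The within-participant CV is per-subject
SD/mean × 100 with non-positive means excluded, summarized as the mean of
per-subject CVs (per-subject-then-average, stated because the pooling order
is a genuine convention choice). The two-way mixed-effects ICC point
estimates follow the Shrout–Fleiss forms from the two-way mean squares
(no interaction term):

    single consistency  = (MSR − MSE) / (MSR + (k−1) MSE)
    average consistency = (MSR − MSE) / MSR
    single agreement    = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE)/n)
    average agreement   = (MSR − MSE) / (MSR + (MSC − MSE)/n)

Confidence intervals are not computed (point estimates only). Likert data
are treated as plain integers.

## Pipeline and determinism

`run_study` consumes a manifest (subject, sequence, CR path, DLR path),
computes reference metrics with CR as the reference, no-reference metrics
per member, and the three features per detector per member; it emits
long-format per-pair CSV, per-sequence mean ± SD summaries, paired-test
tables (both Wilcoxon and paired t), cross-detector CV/ICC tables, and a
JSON run log that materializes every parameter. Unreadable rows are skipped
and logged (exit code 2 on partial runs). Outputs are byte-identical across
reruns for a fixed manifest and seed; non-finite values are serialized as
"inf"/"nan", never dropped.

## Problem sizes

The default test and acceptance workloads use 256×256 phantoms, 25-pair
cohorts, 100 random 32×32 images for the steepness oracle, 5-point blur
sweeps and 50 random 10×3 tables for the ICC oracle — sizes at which every
check runs in seconds while keeping the edge statistics stable (≈600 edge
pixels per phantom per detector).

## Known limitations

* Roberts under noise keeps only the strongest ridges (the guarded
  threshold is conservative for a 2×2 kernel), so its edge counts drop on
  noisy images; features remain comparable because they are measured on the
  shared gradient.
* Edge width saturates once the transition outgrows the profile half-length
  (downward bias for σ ≳ 2 at the 5-px default); widen `half_length` for
  heavily blurred material.
* PSI on very noisy images can be inflated by noise-created narrow
  "edges" for individual subjects; cohort means remain ordered.
* No 3D/multi-frame support, no registration, no Rician noise, no ROI
  restriction.
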