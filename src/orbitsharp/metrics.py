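"""Image quality metrics: SSIM, MS-SSIM, SNR/PSNR, blur measures, PSI.

Reference metrics compare a test image against a reference of equal shape
(here: the deep-learning reconstruction against the conventional one);
no-reference metrics score a single image. All operate on normalized
[0, 1] images (dynamic range 1).

A small plugin registry lets users add external metrics (e.g. FSIM or WASH
implementations) under the same reporting schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter, uniform_filter

from .edges import detect_edges
from .image import GrayImage, compute_gradient

__all__ = [
    "MetricReport",
    "ssim",
    "ms_ssim",
    "psnr",
    "snr_ref",
    "blur_percentage",
    "perceptual_blur_metric",
    "psi",
    "register_metric",
    "get_metric",
    "REFERENCE_METRICS",
    "NOREF_METRICS",
]

MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class MetricReport:
    name: str
    value: float
    is_reference_metric: bool
    parameters: dict = field(default_factory=dict)
    reference_id: str = ""
    test_id: str = ""
    image_id: str = ""
    valid: bool = True


def _check_pair(ref: GrayImage, test: GrayImage) -> None:
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    ref.require_normalized("reference metric")
    test.require_normalized("reference metric")
    ref.require_min_size()


def _ssim_terms(x, y, sigma, k1, k2, data_range):
    """Mean SSIM and mean contrast-structure term (Wang et al. construction).

    Gaussian-weighted local statistics (11-tap window for sigma=1.5),
    population covariance, border strip of the filter radius cropped.
    """
    filt = dict(sigma=sigma, truncate=3.5, mode="reflect")
    ux = gaussian_filter(x, **filt)
    uy = gaussian_filter(y, **filt)
    uxx = gaussian_filter(x * x, **filt)
    uyy = gaussian_filter(y * y, **filt)
    uxy = gaussian_filter(x * y, **filt)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    lum = (2 * ux * uy + c1) / (ux**2 + uy**2 + c1)
    cs = (2 * vxy + c2) / (vx + vy + c2)
    pad = int(3.5 * sigma + 0.5)
    sl = (slice(pad, -pad or None),) * 2
    return float((lum * cs)[sl].mean()), float(cs[sl].mean())


def ssim(
    ref: GrayImage,
    test: GrayImage,
    *,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
) -> float:
    """Structural similarity index, mean over the image.

    Defaults are the standard ones: 11x11 Gaussian window (sigma 1.5),
    K1=0.01, K2=0.03, dynamic range 1 on the normalized scale.
    """
    _check_pair(ref, test)
    val, _ = _ssim_terms(ref.pixels, test.pixels, sigma, k1, k2, data_range)
    return val


def ms_ssim(
    ref: GrayImage,
    test: GrayImage,
    *,
    weights: tuple[float, ...] = MS_SSIM_WEIGHTS,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
) -> float:
    """Multi-scale SSIM: weighted product of contrast-structure terms over
    dyadic scales, with the full SSIM at the coarsest scale.

    Images too small for all scales (min side < 11 * 2^(L-1)) use fewer
    scales with the weights renormalized; a warning is emitted.
    """
    _check_pair(ref, test)
    win = int(2 * int(3.5 * sigma + 0.5) + 1)
    max_levels = len(weights)
    side = min(ref.shape)
    levels = max(1, min(max_levels, int(np.floor(np.log2(side / win))) + 1))
    w = np.asarray(weights[:levels], dtype=float)
    if levels < max_levels:
        warnings.warn(
            f"image side {side} supports only {levels} MS-SSIM scales; "
            "weights renormalized"
        )
        w = w / w.sum()
    x, y = ref.pixels, test.pixels
    terms = []
    for lev in range(levels):
        m, cs = _ssim_terms(x, y, sigma, k1, k2, data_range)
        terms.append(m if lev == levels - 1 else cs)
        if lev < levels - 1:
            x = uniform_filter(x, size=2)[::2, ::2]
            y = uniform_filter(y, size=2)[::2, ::2]
    terms = np.maximum(np.asarray(terms), 1e-12)  # guard negative cs under **
    return float(np.prod(terms**w))


def psnr(ref: GrayImage, test: GrayImage, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    _check_pair(ref, test)
    mse = float(np.mean((ref.pixels - test.pixels) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def snr_ref(ref: GrayImage, test: GrayImage) -> float:
    """Reference SNR in dB: 10*log10(sum(ref^2) / sum((ref-test)^2))."""
    _check_pair(ref, test)
    noise = float(np.sum((ref.pixels - test.pixels) ** 2))
    if noise == 0:
        return float("inf")
    return 10.0 * np.log10(float(np.sum(ref.pixels**2)) / noise)


def _hf_energy(p: np.ndarray) -> float:
    gy, gx = np.gradient(p)
    return float(np.hypot(gx, gy).mean())


def blur_percentage(ref: GrayImage, test: GrayImage) -> float:
    """Reference blur measure in percent: 0 for an identical image, 100 for a
    completely blurred (constant) one.

    Computed as the relative loss of high-frequency energy,
    ``100 * max(0, 1 - HF(test)/HF(ref))`` with HF the mean
    central-difference gradient magnitude; clamped to [0, 100]. A constant
    reference has no high-frequency content and returns 0 with a warning.
    """
    _check_pair(ref, test)
    hf_ref = _hf_energy(ref.pixels)
    if hf_ref == 0:
        warnings.warn("reference image has no gradient content; blur percentage = 0")
        return 0.0
    hf_test = _hf_energy(test.pixels)
    return float(np.clip(100.0 * (1.0 - hf_test / hf_ref), 0.0, 100.0))


def perceptual_blur_metric(img: GrayImage, filter_length: int = 9) -> float:
    """No-reference perceptual blur in [0, 1]; 0 = sharpest, 1 = worst.

    Re-blur construction: the image is strongly low-pass filtered with
    horizontal and vertical box filters (length 9) and the total absolute
    neighbor difference is compared before and after. A sharp image loses
    much of its neighbor variation under re-blurring (value near 0); an
    already blurred image loses little (value near 1). The final value is
    the worse (larger) of the two directions. A constant image is maximally
    blurred by convention (1.0, with a warning).
    """
    img.require_normalized("perceptual_blur_metric")
    img.require_min_size()
    p = img.pixels
    kernel = np.full(filter_length, 1.0 / filter_length)
    out = []
    for axis in (0, 1):
        blurred = correlate1d(p, kernel, axis=axis, mode="nearest")
        d_orig = np.abs(np.diff(p, axis=axis))
        d_blur = np.abs(np.diff(blurred, axis=axis))
        s_orig = d_orig.sum()
        if s_orig == 0:
            out.append(1.0)
            continue
        # variation destroyed by re-blurring, relative to the original
        v = np.maximum(0.0, d_orig - d_blur).sum()
        out.append(float((s_orig - v) / s_orig))
    val = max(out)
    if val >= 1.0 and np.ptp(p) == 0:
        warnings.warn("constant image: perceptual blur metric = 1 by convention")
    return float(np.clip(val, 0.0, 1.0))


def psi(
    img: GrayImage,
    *,
    block_size: int = 32,
    top_fraction: float = 0.22,
    w_jnb: float = 3.0,
    clamp_jnb: bool = False,
    min_width: float = 0.8,
    detector: str = "sobel",
    half_length: float = 5.0,
    spacing: float = 0.25,
    contrast_floor: float = 0.05,
) -> float:
    """Perceptual Sharpness Index: sharpness from local edge-width statistics.

    Strong edges are located per ``block_size`` blocks; their 10-90% widths
    are measured along the local gradient direction (the gradient-normal
    profile needs no slope correction for edge orientation). Local sharpness
    is the reciprocal width, with widths floored at ``min_width`` (the width
    of an ideal discrete step under bilinear sampling — nothing sharper is
    measurable). The index is the mean of the top ``top_fraction`` of block
    sharpness values, so it tracks the sharpest structures, and it decreases
    continuously as blur widens edges. ``w_jnb`` marks the just-noticeable
    blur width; with ``clamp_jnb=True`` widths below it are treated as
    maximally sharp (sharpness capped at 1/w_jnb).

    Raises ValueError for an edge-free image.
    """
    from .features import edge_widths  # local import to avoid cycle

    img.require_normalized("psi")
    img.require_min_size()
    edges = detect_edges(img, detector)
    if edges.n_edge_pixels == 0:
        raise ValueError("no edges detected: PSI undefined")
    grad = compute_gradient(img)
    widths, _, n_valid = edge_widths(
        img, edges, grad=grad, half_length=half_length,
        spacing=spacing, contrast_floor=contrast_floor,
    )
    if n_valid == 0:
        raise ValueError("no valid edge widths: PSI undefined")
    coords = np.argwhere(edges.mask)
    ok = np.isfinite(widths)
    w = np.maximum(widths[ok], min_width)
    if clamp_jnb:
        w = np.maximum(w, 0.0)
        sharp = np.minimum(1.0 / w, 1.0 / w_jnb)
    else:
        sharp = 1.0 / w
    block_ids = (coords[ok, 0] // block_size) * (
        img.width // block_size + 1
    ) + (coords[ok, 1] // block_size)
    # per-block sharpness = sharpest edge in the block
    order = np.argsort(block_ids)
    ids_sorted = block_ids[order]
    sharp_sorted = sharp[order]
    boundaries = np.nonzero(np.diff(ids_sorted))[0] + 1
    block_sharp = np.maximum.reduceat(sharp_sorted, np.r_[0, boundaries])
    k = max(1, int(np.ceil(top_fraction * block_sharp.size)))
    top = np.sort(block_sharp)[::-1][:k]
    return float(top.mean())


# ---------------------------------------------------------------------------
# metric registry (pluggable interface for external metrics such as FSIM/WASH)

REFERENCE_METRICS: dict[str, Callable] = {
    "ssim": ssim,
    "ms_ssim": ms_ssim,
    "psnr": psnr,
    "snr": snr_ref,
    "blur_percentage": blur_percentage,
}
NOREF_METRICS: dict[str, Callable] = {
    "perceptual_blur": perceptual_blur_metric,
    "psi": psi,
}


def register_metric(name: str, fn: Callable, *, reference: bool) -> None:
    """Register an external metric under the standard reporting schema.

    Reference metrics are called as ``fn(ref, test)``, no-reference metrics
    as ``fn(img)``; both must return a float.
    """
    table = REFERENCE_METRICS if reference else NOREF_METRICS
    if name in REFERENCE_METRICS or name in NOREF_METRICS:
        raise ValueError(f"metric {name!r} already registered")
    table[name] = fn


def get_metric(name: str) -> tuple[Callable, bool]:
    """Return (callable, is_reference_metric) for a registered metric name."""
    if name in REFERENCE_METRICS:
        return REFERENCE_METRICS[name], True
    if name in NOREF_METRICS:
        return NOREF_METRICS[name], False
    raise KeyError(f"unknown metric {name!r}")
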