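"""Binary edge maps from the three classic detectors: Roberts, Sobel, Canny.

The detectors only *select* edge pixels; all sharpness features are then
measured on the underlying image/gradient, so detector choice is a
preprocessing step whose influence is quantified separately (cross-detector
agreement statistics in :mod:`orbitsharp.stats`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import feature as skfeature
from skimage import filters as skfilters

from .image import GrayImage, compute_gradient

DETECTORS = ("roberts", "sobel", "canny")

__all__ = ["EdgeMap", "detect_edges", "auto_threshold", "DETECTORS"]


@dataclass
class EdgeMap:
    """Boolean edge mask plus provenance (detector name, thresholds used)."""

    mask: np.ndarray
    detector: str
    threshold_used: float | tuple[float, float]
    params: dict | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("edge mask must be 2D")

    @property
    def n_edge_pixels(self) -> int:
        return int(self.mask.sum())


NOISE_FLOOR_FACTOR = 4.0  # ~4.7x Rayleigh scale: above the noise bulk


def auto_threshold(magnitude: np.ndarray, policy: str = "otsu"):
    """Threshold(s) for a non-negative gradient-magnitude grid.

    ``"otsu"``: Otsu split of the nonzero magnitudes (0 if none; half the
    value if all nonzero magnitudes are equal), guarded from below by a
    noise floor of ``NOISE_FLOOR_FACTOR`` times the median magnitude of the
    whole grid. Otsu alone under-thresholds when edge pixels are rare and
    additive noise fills the histogram; the median of the full grid
    estimates the Rayleigh noise scale on noisy images and is 0 on
    noise-free ones (flat interiors), where the guard is inert.
    ``"canny"``: ``(0.4*t, t)`` with t the guarded Otsu value.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if np.any(magnitude < 0):
        raise ValueError("gradient magnitude must be non-negative")
    nz = magnitude[magnitude > 0]
    if nz.size == 0:
        t = 0.0
    elif np.ptp(nz) == 0:
        t = float(nz[0]) / 2.0
    else:
        t = float(skfilters.threshold_otsu(nz))
        t = max(t, NOISE_FLOOR_FACTOR * float(np.median(magnitude)))
    if policy == "otsu":
        return t
    if policy == "canny":
        # hysteresis floods through noise unless the LOW threshold also
        # clears the noise floor, so raise t until 0.4*t does
        if nz.size and np.ptp(nz) > 0:
            t = max(t, NOISE_FLOOR_FACTOR * float(np.median(magnitude)) / 0.4)
        return (0.4 * t, t)
    raise ValueError(f"unknown threshold policy {policy!r}")


def _nonmax_suppress(mag: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Keep pixels that are local maxima of `mag` along the gradient direction.

    Direction is quantized to 4 neighbor axes; ties are kept so that a
    symmetric two-pixel step edge retains both columns.
    """
    H, W = mag.shape
    keep = np.zeros((H, W), dtype=bool)
    angle = np.arctan2(gy, gx)  # [-pi, pi]
    # quantize to 0, 45, 90, 135 degrees
    sector = (np.round(angle / (np.pi / 4)).astype(int)) % 4
    padded = np.pad(mag, 1, mode="constant")
    offs = {0: ((0, 1), (0, -1)), 1: ((1, 1), (-1, -1)),
            2: ((1, 0), (-1, 0)), 3: ((1, -1), (-1, 1))}
    for s, ((dr1, dc1), (dr2, dc2)) in offs.items():
        sel = sector == s
        n1 = padded[1 + dr1 : H + 1 + dr1, 1 + dc1 : W + 1 + dc1]
        n2 = padded[1 + dr2 : H + 1 + dr2, 1 + dc2 : W + 1 + dc2]
        keep |= sel & (mag >= n1) & (mag >= n2)
    return keep


def detect_edges(
    img: GrayImage,
    detector: str = "sobel",
    *,
    threshold: float | None = None,
    sigma: float = 1.0,
    low: float | None = None,
    high: float | None = None,
    thin: bool = True,
    exclude_border: bool = True,
) -> EdgeMap:
    """Detect edges with Roberts (2x2 diagonal kernels), Sobel (3x3) or Canny.

    Roberts/Sobel threshold their own gradient magnitude, by default at the
    Otsu split of nonzero magnitudes, and are thinned by non-maximum
    suppression along the central-difference gradient so edge pixels
    approximate one-pixel ridges (``thin=False`` keeps the raw band).
    Canny uses Gaussian presmoothing (``sigma``), non-maximum suppression and
    hysteresis with ``(low, high)``; when not given, ``high`` is the Otsu
    split of the smoothed gradient magnitude and ``low = 0.4*high``.

    The outermost 1-px frame is excluded by default: gradients there are
    one-sided and profile lines would leave the image.
    """
    if detector not in DETECTORS:
        raise ValueError(f"unknown detector {detector!r}; choose from {DETECTORS}")
    img.require_normalized("detect_edges")
    img.require_min_size()
    p = img.pixels

    if detector == "canny":
        if low is None or high is None:
            from scipy.ndimage import gaussian_filter, sobel

            # thresholds live in canny's own magnitude units
            # (unnormalized Sobel of the Gaussian-smoothed image)
            sm = gaussian_filter(p, sigma)
            mag = np.hypot(sobel(sm, axis=0), sobel(sm, axis=1))
            auto_low, auto_high = auto_threshold(mag, "canny")
            low = auto_low if low is None else low
            high = auto_high if high is None else high
        if high > 0 and low >= high:
            raise ValueError(f"Canny requires low < high, got ({low}, {high})")
        if high <= 0:
            mask = np.zeros_like(p, dtype=bool)
        else:
            mask = skfeature.canny(p, sigma=sigma, low_threshold=low, high_threshold=high)
        thr: float | tuple[float, float] = (float(low), float(high))
        params = {"sigma": sigma, "low": float(low), "high": float(high)}
    else:
        mag = skfilters.roberts(p) if detector == "roberts" else skfilters.sobel(p)
        mag[mag < 1e-12] = 0.0  # squash float rounding on flat fields
        t = auto_threshold(mag) if threshold is None else float(threshold)
        mask = mag > t if t > 0 else np.zeros_like(mag, dtype=bool)
        if thin and mask.any():
            g = compute_gradient(img)
            mask &= _nonmax_suppress(mag, g.gx, g.gy)
        thr = float(t)
        params = {"threshold": float(t), "thin": thin}

    if exclude_border:
        mask = mask.copy()
        mask[0, :] = mask[-1, :] = False
        mask[:, 0] = mask[:, -1] = False
    return EdgeMap(mask=mask, detector=detector, threshold_used=thr, params=params)
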