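"""Edge sharpness features: mean edge steepness, 10-90% edge width, edge contrast.

This is the core computation of the toolkit. Given a normalized image and a
binary edge map, three per-edge-pixel quantities are extracted and averaged:

* **steepness** — the maximum Euclidean gradient magnitude (central
  differences) in a small window around the edge pixel; the local rate of
  intensity change, intensity/px.
* **width** — the distance over which intensity rises from 10% to 90% of its
  full local contrast along a profile line cast through the edge pixel in
  the gradient direction; the discrete edge-spread-function rise distance,
  in px. For a step blurred by a Gaussian of SD sigma the true value is
  2.5631*sigma.
* **contrast** — max minus min intensity in a local window around the edge
  pixel, on the normalized [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, maximum_filter, minimum_filter

from .edges import EdgeMap, detect_edges
from .image import GradientField, GrayImage, compute_gradient

# 10-90 rise distance of a Gaussian-blurred step, per unit sigma
ERF_RISE_FACTOR = 2.5631

__all__ = [
    "EdgeProfile",
    "EdgeFeatureResult",
    "edge_steepness",
    "extract_edge_profile",
    "edge_width",
    "edge_widths",
    "edge_contrast",
    "summarize_edge_features",
    "ERF_RISE_FACTOR",
]


@dataclass
class EdgeProfile:
    """Interpolated intensity samples along the gradient direction.

    ``samples`` has odd length with the edge pixel at ``center_index``;
    consecutive samples are ``spacing`` px apart. Oriented so that intensity
    increases with sample index. ``valid`` is False when the profile would
    leave the image or the gradient vanished at the pixel.
    """

    samples: np.ndarray
    spacing: float
    center_index: int
    direction: tuple[float, float]
    valid: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.valid:
            if self.samples.size % 2 != 1:
                raise ValueError("profile sample count must be odd")
            if self.spacing <= 0:
                raise ValueError("profile spacing must be positive")


@dataclass
class EdgeFeatureResult:
    """Per-image summary of the three edge-sharpness features."""

    detector: str
    mean_steepness: float
    mean_width_px: float
    mean_contrast: float
    n_edge_pixels: int
    n_valid_widths: int
    valid: bool = True
    params: dict = field(default_factory=dict)
    steepness_values: np.ndarray | None = None
    width_values: np.ndarray | None = None
    contrast_values: np.ndarray | None = None
    source_id: str = ""


PROFILE_INTERP_ORDER = 3  # cubic: tracks the erf edge-spread form within ~1%


def edge_steepness(
    img: GrayImage,
    edges: EdgeMap,
    neighborhood: int = 3,
    grad: GradientField | None = None,
) -> tuple[np.ndarray, float]:
    """Max gradient magnitude in an odd ``neighborhood`` window per edge pixel.

    Always measured on the central-difference gradient of the image itself,
    whatever detector produced the edge map. Windows are clipped at borders.
    Returns (per-pixel values, their mean). Raises on an empty edge map.
    """
    _check_window(neighborhood)
    img.require_normalized("edge_steepness")
    if edges.n_edge_pixels == 0:
        raise ValueError("edge map is empty: steepness undefined")
    if grad is None:
        grad = compute_gradient(img)
    # replicate-padding == clipped window for a running maximum
    local_max = maximum_filter(grad.magnitude, size=neighborhood, mode="nearest")
    vals = local_max[edges.mask]
    return vals, float(vals.mean())


def extract_edge_profile(
    img: GrayImage,
    pixel: tuple[int, int],
    grad: GradientField | None = None,
    half_length: float = 5.0,
    spacing: float = 0.25,
    interp_order: int = PROFILE_INTERP_ORDER,
) -> EdgeProfile:
    """Interpolated intensity profile through one edge pixel.

    The line runs along +/- the unit gradient direction at the pixel and is
    oriented low-to-high. ``interp_order`` selects the spline order of the
    sampling (1 = bilinear, 3 = cubic, the default: bilinear chords between
    1-px nodes widen the apparent 10-90 rise of narrow edges by 6-12% for
    blur SDs below ~1.5 px, cubic stays within ~1% of the closed form).
    Profiles whose samples leave the image, or pixels with zero gradient,
    yield ``valid=False``.
    """
    img.require_normalized("extract_edge_profile")
    if grad is None:
        grad = compute_gradient(img)
    r, c = pixel
    samples, ok, direction = _profiles_batch(
        img.pixels, np.array([[r, c]]), grad, half_length, spacing, interp_order
    )
    n = samples.shape[1]
    if not ok[0]:
        return EdgeProfile(np.empty(0), spacing, 0, (0.0, 0.0), valid=False)
    return EdgeProfile(samples[0], spacing, (n - 1) // 2, tuple(direction[0]), valid=True)


def _profiles_batch(
    pixels: np.ndarray,
    coords: np.ndarray,
    grad: GradientField,
    half_length: float,
    spacing: float,
    interp_order: int = PROFILE_INTERP_ORDER,
):
    """Vectorized profile extraction for N edge pixels.

    Returns (samples (N, M), valid (N,), directions (N, 2) as (gx, gy) unit
    vectors). Invalid rows (zero gradient or out-of-bounds samples) hold NaN.
    """
    H, W = pixels.shape
    rows = coords[:, 0]
    cols = coords[:, 1]
    gx = grad.gx[rows, cols]
    gy = grad.gy[rows, cols]
    norm = np.hypot(gx, gy)
    ok = norm > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        dx = np.where(ok, gx / norm, 0.0)
        dy = np.where(ok, gy / norm, 0.0)

    n_half = int(round(half_length / spacing))
    t = np.arange(-n_half, n_half + 1) * spacing  # (M,)
    samp_r = rows[:, None] + t[None, :] * dy[:, None]
    samp_c = cols[:, None] + t[None, :] * dx[:, None]
    inside = (
        (samp_r.min(axis=1) >= 0)
        & (samp_r.max(axis=1) <= H - 1)
        & (samp_c.min(axis=1) >= 0)
        & (samp_c.max(axis=1) <= W - 1)
    )
    ok &= inside
    samples = np.full(samp_r.shape, np.nan)
    if ok.any():
        flat = map_coordinates(
            pixels,
            [samp_r[ok].ravel(), samp_c[ok].ravel()],
            order=interp_order,
            mode="nearest",
        )
        samples[ok] = flat.reshape(ok.sum(), -1)
        # orient low -> high by comparing end means
        k = max(1, n_half // 4)
        lo = np.nanmean(samples[:, :k], axis=1)
        hi = np.nanmean(samples[:, -k:], axis=1)
        flip = ok & (hi < lo)
        samples[flip] = samples[flip, ::-1]
        dx = np.where(flip, -dx, dx)
        dy = np.where(flip, -dy, dy)
    return samples, ok, np.column_stack([dx, dy])


def edge_width(profile: EdgeProfile, contrast_floor: float = 0.05) -> float:
    """10-90% rise distance of one profile, in px, or NaN when invalid.

    Full contrast = max - min of the samples; the 10% and 90% levels are
    crossed with sub-sample linear interpolation, taking the crossing nearest
    the profile center on each side (which keeps neighboring structures from
    inflating the width). Profiles with contrast below ``contrast_floor`` or
    without both crossings are invalid.
    """
    if not profile.valid:
        return float("nan")
    return _width_from_samples(profile.samples, profile.spacing, contrast_floor)


def _width_from_samples(s: np.ndarray, spacing: float, contrast_floor: float) -> float:
    smin = float(np.min(s))
    smax = float(np.max(s))
    contrast = smax - smin
    if contrast < contrast_floor:
        return float("nan")
    l10 = smin + 0.1 * contrast
    l90 = smin + 0.9 * contrast
    center = (s.size - 1) / 2.0
    p10 = _nearest_upcrossing(s, l10, center)
    p90 = _nearest_upcrossing(s, l90, center)
    if p10 is None or p90 is None or p90 <= p10:
        return float("nan")
    return (p90 - p10) * spacing


def _nearest_upcrossing(s: np.ndarray, level: float, center: float) -> float | None:
    """Sub-sample position of the upward crossing of `level` nearest `center`."""
    below = s[:-1] <= level
    above = s[1:] > level
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return None
    denom = s[idx + 1] - s[idx]
    frac = np.where(denom > 0, (level - s[idx]) / denom, 0.0)
    pos = idx + frac
    return float(pos[np.argmin(np.abs(pos - center))])


def edge_widths(
    img: GrayImage,
    edges: EdgeMap,
    grad: GradientField | None = None,
    half_length: float = 5.0,
    spacing: float = 0.25,
    contrast_floor: float = 0.05,
    interp_order: int = PROFILE_INTERP_ORDER,
) -> tuple[np.ndarray, float, int]:
    """10-90% widths for every edge pixel; returns (widths, mean, n_valid).

    Invalid profiles/widths are NaN and excluded from the mean.
    """
    img.require_normalized("edge_widths")
    if edges.n_edge_pixels == 0:
        raise ValueError("edge map is empty: widths undefined")
    if grad is None:
        grad = compute_gradient(img)
    coords = np.argwhere(edges.mask)
    samples, ok, _ = _profiles_batch(
        img.pixels, coords, grad, half_length, spacing, interp_order
    )
    widths = np.full(coords.shape[0], np.nan)
    for i in np.nonzero(ok)[0]:
        widths[i] = _width_from_samples(samples[i], spacing, contrast_floor)
    valid = np.isfinite(widths)
    mean = float(widths[valid].mean()) if valid.any() else float("nan")
    return widths, mean, int(valid.sum())


def edge_contrast(
    img: GrayImage, edges: EdgeMap, neighborhood: int = 7
) -> tuple[np.ndarray, float]:
    """Max-minus-min intensity in an odd window around each edge pixel.

    The window half-width must be at least half the widest 10-90 transition
    under study or the measured contrast clips to a fraction of the true
    edge contrast, and more strongly so for blurrier images; the default
    7x7 spans transitions from edge blur up to ~2.3 px SD.
    """
    _check_window(neighborhood)
    img.require_normalized("edge_contrast")
    if edges.n_edge_pixels == 0:
        raise ValueError("edge map is empty: contrast undefined")
    p = img.pixels
    rng = maximum_filter(p, size=neighborhood, mode="nearest") - minimum_filter(
        p, size=neighborhood, mode="nearest"
    )
    vals = rng[edges.mask]
    return vals, float(vals.mean())


def summarize_edge_features(
    img: GrayImage,
    detector: str = "sobel",
    *,
    steepness_window: int = 3,
    contrast_window: int = 7,
    half_length: float = 5.0,
    spacing: float = 0.25,
    contrast_floor: float = 0.05,
    detector_params: dict | None = None,
    keep_per_pixel: bool = False,
) -> EdgeFeatureResult:
    """Run one detector and all three features on a shared edge map."""
    img.require_normalized("summarize_edge_features")
    img.require_min_size()
    edges = detect_edges(img, detector, **(detector_params or {}))
    params = {
        "steepness_window": steepness_window,
        "contrast_window": contrast_window,
        "half_length": half_length,
        "spacing": spacing,
        "contrast_floor": contrast_floor,
        "threshold_used": edges.threshold_used,
    }
    if edges.n_edge_pixels == 0:
        return EdgeFeatureResult(
            detector=detector,
            mean_steepness=float("nan"),
            mean_width_px=float("nan"),
            mean_contrast=float("nan"),
            n_edge_pixels=0,
            n_valid_widths=0,
            valid=False,
            params=params,
            source_id=img.source_id,
        )
    grad = compute_gradient(img)
    s_vals, s_mean = edge_steepness(img, edges, steepness_window, grad=grad)
    w_vals, w_mean, n_valid = edge_widths(
        img, edges, grad=grad, half_length=half_length,
        spacing=spacing, contrast_floor=contrast_floor,
    )
    c_vals, c_mean = edge_contrast(img, edges, contrast_window)
    return EdgeFeatureResult(
        detector=detector,
        mean_steepness=s_mean,
        mean_width_px=w_mean,
        mean_contrast=c_mean,
        n_edge_pixels=edges.n_edge_pixels,
        n_valid_widths=n_valid,
        valid=True,
        params=params,
        steepness_values=s_vals if keep_per_pixel else None,
        width_values=w_vals if keep_per_pixel else None,
        contrast_values=c_vals if keep_per_pixel else None,
        source_id=img.source_id,
    )


def _check_window(n: int) -> None:
    if n < 1 or n % 2 != 1:
        raise ValueError(f"neighborhood must be a positive odd integer, got {n}")
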