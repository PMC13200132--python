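"""Grayscale image container, file I/O, normalization and gradients.

Everything downstream (edge maps, sharpness features, quality metrics)
operates on :class:`GrayImage`, a plain 2D float array with a normalization
flag, and on :class:`GradientField`, the central-difference gradient shared
by all gradient-based measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GrayImage",
    "GradientField",
    "load_image",
    "save_image",
    "normalize_intensity",
    "compute_gradient",
]


@dataclass
class GrayImage:
    """A 2D grayscale image with finite real intensities.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensity grid, row-major, 0-based, pixel centers at integer
        coordinates. Stored as float64.
    source_id : str
        Opaque label (file path, phantom id, ...).
    normalized : bool
        True once intensities have been rescaled to [0, 1].
    norm_warning : bool
        Set when normalization hit a degenerate (constant) input.
    """

    pixels: np.ndarray
    source_id: str = ""
    normalized: bool = False
    norm_warning: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage requires a 2D array, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage intensities must be finite")
        if self.normalized:
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError("normalized image has intensities outside [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def require_normalized(self, op: str = "operation") -> None:
        if not self.normalized:
            raise ValueError(f"{op} requires a normalized image; call normalize_intensity first")

    def require_min_size(self, n: int = 8) -> None:
        if self.height < n or self.width < n:
            raise ValueError(f"image must be at least {n}x{n}, got {self.shape}")


@dataclass
class GradientField:
    """Central-difference gradient of an image.

    ``gx`` is the horizontal (column-direction) derivative, ``gy`` the
    vertical (row-direction) derivative, both in intensity per pixel.
    ``magnitude`` is the Euclidean norm sqrt(gx^2 + gy^2), a rotationally
    invariant measure of the local intensity transition rate.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.magnitude is None:
            self.magnitude = np.hypot(self.gx, self.gy)
        if not (self.gx.shape == self.gy.shape == self.magnitude.shape):
            raise ValueError("gradient components must share one shape")


def load_image(path: str | Path, *, slice_index: int | None = None) -> GrayImage:
    """Read a 2D grayscale raster (PNG, TIFF, single-frame DICOM, NIfTI slice).

    DICOM rescale slope/intercept are applied. Multi-channel (RGB) inputs and
    >2D rasters without a ``slice_index`` are rejected. The returned image is
    un-normalized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        arr = _load_nifti_slice(path, slice_index)
    elif suffixes.endswith((".dcm", ".dicom", ".ima")):
        arr = _load_dicom(path)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            raise ValueError(f"{path.name}: multi-channel (RGB/RGBA) input not supported")
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected 2D data, got shape {arr.shape}")
    return GrayImage(arr.astype(np.float64), source_id=str(path))


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: multi-frame DICOM not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr.astype(np.float64) * slope + intercept


def _load_nifti_slice(path: Path, slice_index: int | None) -> np.ndarray:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    vol = np.squeeze(vol)
    if vol.ndim == 2:
        return vol
    if vol.ndim == 3:
        if slice_index is None:
            raise ValueError(f"{path.name}: 3D volume requires a slice index")
        return vol[:, :, slice_index]
    raise ValueError(f"{path.name}: unsupported dimensionality {vol.ndim}")


def save_image(img: GrayImage, path: str | Path, *, bit_depth: int = 16) -> None:
    """Write a 16-bit (or 8-bit) PNG/TIFF fixture.

    Normalized images are scaled to the full integer range; un-normalized
    integer-valued images in range are stored verbatim.
    """
    import imageio.v3 as iio

    path = Path(path)
    vmax = 2**bit_depth - 1
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    p = img.pixels
    if img.normalized or (p.min() >= 0.0 and p.max() <= 1.0):
        data = np.round(p * vmax).astype(dtype)
    else:
        if p.min() < 0 or p.max() > vmax:
            raise ValueError(f"pixel values outside [0, {vmax}]; normalize first")
        data = np.round(p).astype(dtype)
    iio.imwrite(path, data)


def normalize_intensity(
    img: GrayImage, clip_percentiles: tuple[float, float] | None = None
) -> GrayImage:
    """Linearly rescale intensities so min -> 0 and max -> 1.

    With ``clip_percentiles=(p_low, p_high)`` the intensities are first
    clipped to those percentiles (useful for noisy tails). A constant image
    maps to all zeros with ``norm_warning`` set instead of raising, so batch
    pipelines do not abort on degenerate inputs. Idempotent.
    """
    p = img.pixels
    if clip_percentiles is not None:
        lo, hi = np.percentile(p, clip_percentiles)
        p = np.clip(p, lo, hi)
    pmin, pmax = float(p.min()), float(p.max())
    if pmax - pmin <= 0:
        warnings.warn(f"constant image {img.source_id!r}: normalized to all zeros")
        return GrayImage(np.zeros_like(p), img.source_id, normalized=True, norm_warning=True)
    out = (p - pmin) / (pmax - pmin)
    return GrayImage(out, img.source_id, normalized=True)


def compute_gradient(img: GrayImage) -> GradientField:
    """Central-difference gradient with one-sided differences at borders.

    Interior: (I[i+1] - I[i-1]) / 2; first/last row/column: one-sided first
    differences. This is the convention of ``numpy.gradient`` (and of the
    classic MATLAB ``gradient()``), so a linear ramp yields its exact slope
    at every pixel including borders.
    """
    img.require_normalized("compute_gradient")
    gy, gx = np.gradient(img.pixels)
    return GradientField(gx=gx, gy=gy)
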