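import numpy as np
import pytest

from orbitsharp import EllipseShape, GrayImage, PhantomSpec, generate_phantom


@pytest.fixture
def vertical_step():
    """Normalized unit step: columns 0..7 at 0, columns 8..15 at 1."""
    p = np.zeros((16, 16))
    p[:, 8:] = 1.0
    return GrayImage(p, source_id="step", normalized=True)


@pytest.fixture
def disk_spec():
    """Hard-edged disk of radius 30 px centered in a 128x128 canvas."""
    return PhantomSpec(
        size=(128, 128),
        background=0.05,
        shapes=[EllipseShape((64.0, 64.0), (30.0, 30.0), 0.0, 0.8, "disk")],
        edge_sigma=0.0,
        noise_sd=0.0,
    )


@pytest.fixture
def disk_image(disk_spec):
    img, _ = generate_phantom(disk_spec)
    return img


def erf_edge_image(sigma: float, width: int = 128, height: int = 64) -> GrayImage:
    """Vertical edge following the Gaussian edge-spread function Phi(x/sigma)."""
    from scipy.special import ndtr

    x = np.arange(width) - width / 2 + 0.5
    return GrayImage(np.tile(ndtr(x / sigma), (height, 1)),
                     source_id=f"erf{sigma}", normalized=True)
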