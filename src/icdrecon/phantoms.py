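"""Synthetic test images with known cosupport structure.

Provides the canonical 10-ellipse Shepp-Logan head phantom (exactly
piecewise constant at any resolution, since pixel membership is decided by
the pixel centre) and seeded Voronoi piecewise-constant fixtures whose exact
cosupport under the package's difference operators is returned alongside the
image.  Both serve as ground truth for reconstruction experiments: their
directional finite-difference coefficients are zero away from region
boundaries, so the true cosupport covers the vast majority of coefficient
positions.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .operators import (
    CosupportSet,
    DEFAULT_DIRECTIONS,
    FiniteDifferenceOperator,
    true_cosupport,
)
from .sampling import SamplingMask, forward_fourier

__all__ = ["shepp_logan", "piecewise_constant_image", "simulate_measurements"]

# Ellipse table: (intensity, semi-axis x, semi-axis y, x0, y0, rotation deg).
# Geometry is shared; the two variants differ only in the additive
# intensities.  "modified" is the high-contrast set common in the CS-MRI
# literature; "standard" is the original low-contrast set.
_ELLIPSE_GEOMETRY = [
    (0.69, 0.92, 0.0, 0.0, 0.0),
    (0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (0.1100, 0.3100, 0.22, 0.0, -18.0),
    (0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.0230, 0.0460, 0.06, -0.605, 0.0),
]
_INTENSITIES = {
    "modified": [1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
    "standard": [1.0, -0.98, -0.02, -0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01],
}


def shepp_logan(side: int, variant: str = "modified") -> np.ndarray:
    """Render the Shepp-Logan head phantom on a ``side × side`` grid.

    Intensities are additive over the ten ellipses and a pixel belongs to an
    ellipse iff its centre does, so the output is exactly piecewise constant
    with values in [0, 1].  Deterministic: no randomness is involved.
    """
    if side < 16:
        raise ValueError("side must be at least 16")
    try:
        intensities = _INTENSITIES[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; expected 'standard' or 'modified'"
        ) from None
    # pixel-centre coordinates in [-1, 1] x [-1, 1], y axis pointing up
    coords = (2.0 * np.arange(side) + 1.0 - side) / side
    x = coords[np.newaxis, :]
    y = -coords[:, np.newaxis]
    img = np.zeros((side, side))
    for amp, (a, b, x0, y0, phi_deg) in zip(intensities, _ELLIPSE_GEOMETRY):
        phi = np.deg2rad(phi_deg)
        xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
        yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        img[inside] += amp
    return np.clip(img, 0.0, 1.0)


def piecewise_constant_image(
    shape: Tuple[int, int],
    num_regions: int,
    seed: int,
    directions: Tuple[str, ...] = DEFAULT_DIRECTIONS,
) -> Tuple[np.ndarray, CosupportSet]:
    """Seeded Voronoi piecewise-constant fixture with its exact cosupport.

    ``num_regions`` seed points are drawn uniformly over the grid and every
    pixel takes the (distinct) value of its nearest seed (ties resolved by
    the lowest seed index).  Returns the image together with
    ``true_cosupport(image, tol=0)`` under the periodic difference operator
    on ``directions``.
    """
    if num_regions < 1:
        raise ValueError("num_regions must be >= 1")
    rows, cols = shape
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(0, rows, num_regions), rng.uniform(0, cols, num_regions)]
    )
    # distinct, well separated region values in (0, 1]
    values = rng.permutation(num_regions) / num_regions + 1.0 / num_regions
    rr, cc = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5,
                         indexing="ij")
    d2 = (rr[..., None] - pts[:, 0]) ** 2 + (cc[..., None] - pts[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1)  # argmin takes the lowest index on ties
    image = values[labels]
    operator = FiniteDifferenceOperator(shape, directions)
    return image, true_cosupport(image, operator, tol=0.0)


def simulate_measurements(
    image: np.ndarray,
    mask: SamplingMask,
    noise_std: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate k-space acquisition ``y = F_u x`` (noiseless by default).

    ``noise_std > 0`` adds seeded complex Gaussian noise (standard
    deviation per real/imaginary component) for robustness experiments.
    """
    y = forward_fourier(image, mask)
    if noise_std > 0.0:
        rng = np.random.default_rng(seed)
        y = y + noise_std * (
            rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        )
    return y
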