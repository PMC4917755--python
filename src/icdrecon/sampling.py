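"""k-space sampling masks and the undersampled Fourier operator ``F_u``.

MRI acquires samples of the 2-D discrete Fourier transform of the image
(k-space).  Undersampling k-space below the Nyquist count and reconstructing
with a sparsity prior is the compressed-sensing MRI setting this package
targets.  This module generates the three standard undersampling patterns —
radial line trajectories, variable-density random sampling, and Cartesian
phase-encode-line sampling — and implements the measurement operator
``F_u x = (unitary 2-D DFT of x) restricted to the mask`` with its adjoint
(zero-filling followed by the unitary inverse DFT).

Masks are stored in the FFT-native layout (DC at index ``[0, 0]``); the
generators rasterize in the centered-frequency frame and convert with
``np.fft.ifftshift``.  Measurements are ordered by ascending flat index of
the native-layout mask so that ``y`` is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "SamplingMask",
    "radial_mask",
    "variable_density_mask",
    "cartesian_mask",
    "forward_fourier",
    "adjoint_fourier",
]


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space sampling pattern (FFT-native layout, True = sampled)."""

    array: np.ndarray
    scheme: str
    params: dict

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not arr[0, 0]:
            raise ValueError("the DC location (index [0, 0]) must be sampled")
        object.__setattr__(self, "array", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.array.shape

    @property
    def num_samples(self) -> int:
        return int(self.array.sum())

    @property
    def ratio(self) -> float:
        """Realized sampling ratio: sampled cells / total cells."""
        return self.num_samples / self.array.size

    def centered(self) -> np.ndarray:
        """Mask in the centered-frequency frame (DC at ``shape//2``)."""
        return np.fft.fftshift(self.array)

    def metadata(self) -> dict:
        return {
            "scheme": self.scheme,
            "shape": list(self.shape),
            "num_samples": self.num_samples,
            "sampling_ratio": self.ratio,
            "params": self.params,
        }

    def to_json(self) -> str:
        return json.dumps(self.metadata())


def radial_mask(shape: Tuple[int, int], num_lines: int) -> SamplingMask:
    """Radial-trajectory mask: ``num_lines`` straight lines through DC.

    Line ``k`` has angle ``θ_k = kπ/num_lines`` in the centered frame
    (``θ=0`` is the horizontal line).  Each line spans the full grid: it is
    rasterized by stepping one cell along its dominant axis (so a line
    marks ``max(shape)`` nearest-neighbour cells, reaching the grid
    boundary at every angle, corner-to-corner for the diagonals); the
    result is deterministic.
    """
    if num_lines < 1:
        raise ValueError("num_lines must be >= 1")
    rows, cols = shape
    centered = np.zeros(shape, dtype=bool)
    cr, cc = rows // 2, cols // 2
    for k in range(num_lines):
        theta = k * np.pi / num_lines
        ct, st_ = np.cos(theta), np.sin(theta)
        if abs(ct) >= abs(st_):  # more horizontal: one cell per column
            c = np.arange(cols)
            r = np.rint(cr + (c - cc) * (st_ / ct)).astype(int)
        else:  # more vertical: one cell per row
            r = np.arange(rows)
            c = np.rint(cc + (r - cr) * (ct / st_)).astype(int)
        keep = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
        centered[r[keep], c[keep]] = True
    centered[cr, cc] = True  # DC, on every line through the center
    return SamplingMask(
        np.fft.ifftshift(centered),
        scheme="radial",
        params={"num_lines": int(num_lines)},
    )


def _radial_distance(shape: Tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    r = np.arange(rows) - rows // 2
    c = np.arange(cols) - cols // 2
    return np.hypot(*np.meshgrid(r, c, indexing="ij"))


def variable_density_mask(
    shape: Tuple[int, int],
    target_ratio: float,
    seed: int,
    decay_power: float = 3.0,
) -> SamplingMask:
    """Variable-density random mask with a fully sampled low-frequency disc.

    Each centered-frame location is sampled independently with probability
    proportional to ``(1 - r/r_max)^decay_power`` (``r`` the centered radial
    distance), rescaled so the expected sample count matches
    ``target_ratio * n`` after clipping to [0, 1]; a central disc of radius
    ``ceil(0.05 * min(shape))`` is always fully sampled.
    """
    if not 0.0 < target_ratio < 1.0:
        raise ValueError("target_ratio must lie strictly between 0 and 1")
    if decay_power < 0:
        raise ValueError("decay_power must be non-negative")
    rows, cols = shape
    n = rows * cols
    dist = _radial_distance(shape)
    r_max = dist.max()
    base = (1.0 - dist / r_max) ** decay_power

    center_radius = int(np.ceil(0.05 * min(shape)))
    forced = dist <= center_radius
    n_forced = int(forced.sum())
    target_count = target_ratio * n
    if target_count < n_forced:
        raise ValueError(
            f"target_ratio {target_ratio} is below the forced central disc "
            f"({n_forced}/{n} cells); increase the ratio or shrink the image"
        )

    free = ~forced
    need = target_count - n_forced
    base_free = base[free]

    def expected(scale: float) -> float:
        return float(np.minimum(scale * base_free, 1.0).sum())

    # monotone in scale: bisect for the clipped-expectation match
    lo, hi = 0.0, 1.0
    while expected(hi) < need and hi < 1e12:
        hi *= 2.0
    if expected(hi) < need - 0.5:
        raise ValueError(
            "cannot reach the target ratio: density fully saturated after clipping"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < need:
            lo = mid
        else:
            hi = mid
    prob = np.minimum(hi * base, 1.0)

    rng = np.random.default_rng(seed)
    centered = rng.random(shape) < prob
    centered[forced] = True
    return SamplingMask(
        np.fft.ifftshift(centered),
        scheme="variable_density",
        params={
            "target_ratio": float(target_ratio),
            "seed": int(seed),
            "decay_power": float(decay_power),
            "center_radius": center_radius,
        },
    )


def cartesian_mask(
    shape: Tuple[int, int],
    target_ratio: float,
    seed: int,
    decay_power: float = 3.0,
) -> SamplingMask:
    """Cartesian mask: full phase-encode rows, variable-density row choice.

    Exactly ``round(target_ratio * rows)`` rows are sampled: a forced central
    band of ``ceil(0.05 * rows)`` rows around DC plus rows drawn without
    replacement with probability decaying polynomially in the centered row
    distance.  Every sampled row contributes all ``cols`` samples.
    """
    if not 0.0 < target_ratio < 1.0:
        raise ValueError("target_ratio must lie strictly between 0 and 1")
    rows, cols = shape
    k = int(round(target_ratio * rows))
    if k < 1:
        raise ValueError("target_ratio selects zero rows")
    center = rows // 2
    dist = np.abs(np.arange(rows) - center)
    forced = np.flatnonzero(dist <= int(np.ceil(0.05 * rows)))
    if k < len(forced):
        raise ValueError(
            f"target_ratio {target_ratio} selects fewer rows ({k}) than the "
            f"forced central band ({len(forced)})"
        )
    remaining = np.setdiff1d(np.arange(rows), forced)
    weights = (1.0 - dist[remaining] / max(dist.max(), 1)) ** decay_power
    weights = np.maximum(weights, 1e-12)
    rng = np.random.default_rng(seed)
    extra = rng.choice(
        remaining, size=k - len(forced), replace=False, p=weights / weights.sum()
    )
    chosen = np.concatenate([forced, extra])
    centered = np.zeros(shape, dtype=bool)
    centered[chosen, :] = True
    return SamplingMask(
        np.fft.ifftshift(centered),
        scheme="cartesian",
        params={
            "target_ratio": float(target_ratio),
            "seed": int(seed),
            "decay_power": float(decay_power),
            "rows_sampled": int(k),
        },
    )


def forward_fourier(image: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """``F_u x``: unitary 2-D DFT followed by selection of masked locations.

    Measurements are ordered by ascending flat index of the native-layout
    mask.
    """
    image = np.asarray(image)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {mask.shape}"
        )
    spectrum = np.fft.fft2(image, norm="ortho")
    return spectrum.ravel()[mask.array.ravel()]


def adjoint_fourier(measurements: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """``F_uᴴ y``: zero-fill the masked locations, unitary inverse DFT."""
    measurements = np.asarray(measurements)
    if measurements.shape != (mask.num_samples,):
        raise ValueError(
            f"expected {mask.num_samples} measurements, got {measurements.shape}"
        )
    spectrum = np.zeros(mask.shape, dtype=complex)
    spectrum.ravel()[mask.array.ravel()] = measurements
    return np.fft.ifft2(spectrum, norm="ortho")
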