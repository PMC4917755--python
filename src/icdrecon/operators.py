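"""Analysis operators: directional finite differences and an orthonormal wavelet.

The analysis (cosparse) signal model assumes that applying a tall operator
:math:`\\Omega \\in \\mathbb{R}^{p \\times n}` to the vectorised image ``x``
yields a vector ``z = Ω x`` with many *zero* entries.  The number of zeros is
the cosparsity ``l`` and their index set is the cosupport ``Λ``.  For
piecewise-constant images the natural operator is the finite difference: each
row of ``Ω_i`` differences a pixel against one neighbour along direction
``i``.  This module provides four periodic directional difference operators
(vertical, horizontal and the two diagonals), their adjoints, exact-cosupport
extraction, cosupport containers, and an orthonormal multilevel wavelet
transform used by the wavelet-augmented reconstruction variant.

Conventions
-----------
* Images are 2-D arrays (real or complex); coefficient vectors are flat,
  row-major (C order), 0-based.
* Boundaries are periodic (circular), so every directional operator has
  exactly ``p_i = rows * cols`` coefficients and differences wrap around.
* Direction stencils: ``vertical`` differences a pixel against the one below
  (``x[r, c] - x[r+1, c]``), ``horizontal`` against the right neighbour
  (``x[r, c] - x[r, c+1]``), ``diag_main`` against the lower-right
  (``x[r, c] - x[r+1, c+1]``) and ``diag_anti`` against the lower-left
  (``x[r, c] - x[r+1, c-1]``), all indices mod the image shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pywt

__all__ = [
    "DIRECTIONS",
    "AnalysisOperator",
    "FiniteDifferenceOperator",
    "WaveletOperator",
    "CosupportSet",
    "apply_finite_difference",
    "adjoint_finite_difference",
    "restrict_to_cosupport",
    "true_cosupport",
    "wavelet_transform",
    "wavelet_adjoint",
]

#: Ordered canonical direction tags and the (row, col) shift of the
#: neighbour each one differences against.
DIRECTIONS: Dict[str, Tuple[int, int]] = {
    "vertical": (1, 0),
    "horizontal": (0, 1),
    "diag_main": (1, 1),
    "diag_anti": (1, -1),
}

DEFAULT_DIRECTIONS: Tuple[str, ...] = tuple(DIRECTIONS)
TWO_DIRECTIONS: Tuple[str, ...] = ("vertical", "horizontal")


def _check_direction(direction: str) -> Tuple[int, int]:
    try:
        return DIRECTIONS[direction]
    except KeyError:
        raise ValueError(
            f"unknown direction {direction!r}; expected one of {sorted(DIRECTIONS)}"
        ) from None


def apply_finite_difference(image: np.ndarray, direction: str) -> np.ndarray:
    """First-order periodic difference of ``image`` along ``direction``.

    Returns the flat (row-major) length-``rows*cols`` coefficient vector
    ``(Ω_i x)_j = x[r, c] - x[(r+dr) % R, (c+dc) % C]`` where ``j`` is the
    flat index of pixel ``(r, c)``.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    dr, dc = _check_direction(direction)
    diff = image - np.roll(image, shift=(-dr, -dc), axis=(0, 1))
    return diff.ravel()


def adjoint_finite_difference(
    coeffs: np.ndarray, direction: str, image_shape: Tuple[int, int]
) -> np.ndarray:
    """Adjoint ``Ω_iᵀ v`` of the periodic difference, as a 2-D image."""
    dr, dc = _check_direction(direction)
    coeffs = np.asarray(coeffs)
    n = image_shape[0] * image_shape[1]
    if coeffs.shape != (n,):
        raise ValueError(f"coefficient length {coeffs.shape} does not match {n}")
    v = coeffs.reshape(image_shape)
    return v - np.roll(v, shift=(dr, dc), axis=(0, 1))


def restrict_to_cosupport(coeffs: np.ndarray, indices: Iterable[int]) -> np.ndarray:
    """Sub-vector of ``coeffs`` at the given cosupport ``indices``.

    Entries are returned in ascending index order.  Out-of-range indices
    raise ``IndexError``.
    """
    coeffs = np.asarray(coeffs)
    idx = np.asarray(sorted(indices), dtype=np.intp)
    if idx.size == 0:
        return coeffs[:0]
    if idx[0] < 0 or idx[-1] >= coeffs.shape[0]:
        raise IndexError(
            f"cosupport index out of range [0, {coeffs.shape[0]}): "
            f"min {idx[0]}, max {idx[-1]}"
        )
    return coeffs[idx]


@dataclass(frozen=True)
class CosupportSet:
    """Per-direction cosupport index sets ``Λ_i``.

    ``indices`` maps a direction tag to a sorted array of 0-based flat
    coefficient positions where the analysis coefficients are (believed to
    be) zero.  The total cosparsity is ``sum(len(Λ_i))``.
    """

    indices: Mapping[str, np.ndarray]
    coeff_length: int

    def __post_init__(self) -> None:
        clean = {}
        for direction, idx in self.indices.items():
            _check_direction(direction)
            arr = np.unique(np.asarray(idx, dtype=np.intp))
            if arr.size and (arr[0] < 0 or arr[-1] >= self.coeff_length):
                raise IndexError(
                    f"cosupport index out of [0, {self.coeff_length}) in "
                    f"direction {direction!r}"
                )
            clean[direction] = arr
        object.__setattr__(self, "indices", clean)

    @property
    def directions(self) -> Tuple[str, ...]:
        return tuple(self.indices)

    def cosparsity(self, direction: str | None = None) -> int:
        """Number of cosupport indices in one direction, or total."""
        if direction is not None:
            return int(self.indices[direction].size)
        return int(sum(v.size for v in self.indices.values()))

    def mask(self, direction: str) -> np.ndarray:
        """Boolean indicator of ``Λ_i`` over all coefficient positions."""
        m = np.zeros(self.coeff_length, dtype=bool)
        m[self.indices[direction]] = True
        return m

    @classmethod
    def full(cls, directions: Sequence[str], coeff_length: int) -> "CosupportSet":
        """Cosupport equal to the full index set in every direction."""
        all_idx = np.arange(coeff_length, dtype=np.intp)
        return cls({d: all_idx.copy() for d in directions}, coeff_length)

    @classmethod
    def empty(cls, directions: Sequence[str], coeff_length: int) -> "CosupportSet":
        return cls(
            {d: np.empty(0, dtype=np.intp) for d in directions}, coeff_length
        )

    def to_json(self) -> str:
        """Serialize as ``{direction: sorted 0-based index list}``."""
        return json.dumps(
            {d: [int(i) for i in idx] for d, idx in self.indices.items()}
        )

    @classmethod
    def from_json(cls, text: str, coeff_length: int) -> "CosupportSet":
        data = json.loads(text)
        return cls({d: np.asarray(v, dtype=np.intp) for d, v in data.items()},
                   coeff_length)


@dataclass(frozen=True)
class FiniteDifferenceOperator:
    """Multi-directional periodic finite-difference analysis operator.

    Stacks one periodic first-difference block per direction; with periodic
    boundaries every block has ``p_i = rows*cols`` rows, so the full operator
    is ``p = len(directions) * rows * cols`` by ``n`` and is genuinely
    redundant (``p > n``) whenever more than one direction is used.
    """

    image_shape: Tuple[int, int]
    directions: Tuple[str, ...] = DEFAULT_DIRECTIONS
    kind: str = field(default="finite_difference", init=False)

    def __post_init__(self) -> None:
        if len(self.image_shape) != 2:
            raise ValueError("image_shape must be (rows, cols)")
        object.__setattr__(self, "directions", tuple(self.directions))
        if not self.directions:
            raise ValueError("at least one direction is required")
        for d in self.directions:
            _check_direction(d)

    @property
    def n(self) -> int:
        return int(np.prod(self.image_shape))

    @property
    def coeff_length(self) -> int:
        """``p_i`` — coefficient count per direction (= n, periodic)."""
        return self.n

    @property
    def p(self) -> int:
        """Total number of analysis rows across directions."""
        return self.coeff_length * len(self.directions)

    def apply(self, image: np.ndarray, direction: str) -> np.ndarray:
        return apply_finite_difference(image, direction)

    def apply_all(self, image: np.ndarray) -> np.ndarray:
        """All directional coefficients, stacked as ``(ndir, p_i)``."""
        return np.stack([self.apply(image, d) for d in self.directions])

    def adjoint(self, coeffs: np.ndarray, direction: str) -> np.ndarray:
        return adjoint_finite_difference(coeffs, direction, self.image_shape)

    def adjoint_all(self, coeffs: np.ndarray) -> np.ndarray:
        """Sum of per-direction adjoints for stacked ``(ndir, p_i)`` coeffs."""
        out = np.zeros(self.image_shape, dtype=np.asarray(coeffs).dtype)
        for i, d in enumerate(self.directions):
            out = out + self.adjoint(coeffs[i], d)
        return out

    def dense_matrix(self, direction: str) -> np.ndarray:
        """Explicit ``p_i × n`` matrix of one direction (small images only)."""
        if self.n > 4096:
            raise ValueError("dense_matrix is intended for small images")
        dr, dc = _check_direction(direction)
        rows, cols = self.image_shape
        n = self.n
        r, c = np.divmod(np.arange(n), cols)
        neighbour = ((r + dr) % rows) * cols + (c + dc) % cols
        mat = np.zeros((n, n))
        mat[np.arange(n), np.arange(n)] += 1.0
        mat[np.arange(n), neighbour] -= 1.0
        return mat


def true_cosupport(
    image: np.ndarray,
    operator: FiniteDifferenceOperator,
    tol: float = 0.0,
) -> CosupportSet:
    """Exact (or ``tol``-relaxed) cosupport ``Λ_i = {j : |(Ω_i x)_j| ≤ tol}``."""
    if tol < 0:
        raise ValueError("tol must be non-negative")
    indices = {}
    for d in operator.directions:
        mags = np.abs(operator.apply(image, d))
        indices[d] = np.flatnonzero(mags <= tol)
    return CosupportSet(indices, operator.coeff_length)


class WaveletOperator:
    """Orthonormal multilevel 2-D wavelet transform ``Ψ`` with exact adjoint.

    Daubechies-4 (``db4``) with periodization and 4 levels by default: an
    orthogonal transform on the periodic extension, so ``ΨᵀΨ = I`` and the
    adjoint is the inverse.  Complex images are transformed component-wise.
    """

    def __init__(
        self,
        image_shape: Tuple[int, int],
        wavelet: str = "db4",
        levels: int = 4,
    ) -> None:
        rows, cols = image_shape
        div = 2 ** levels
        if rows % div or cols % div:
            raise ValueError(
                f"image shape {image_shape} is not divisible by 2^{levels}"
            )
        self.image_shape = (int(rows), int(cols))
        self.wavelet = wavelet
        self.levels = int(levels)
        # cache the coefficient layout for array <-> coeff-list round trips
        # (pywt warns about deep levels on small grids, but periodization
        # keeps the transform exactly orthogonal at any dyadic depth)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            template = pywt.wavedec2(
                np.zeros(self.image_shape), wavelet, mode="periodization",
                level=levels,
            )
        _, self._slices = pywt.coeffs_to_array(template)
        self.kind = "wavelet"

    @property
    def coeff_length(self) -> int:
        return int(np.prod(self.image_shape))

    def _forward_real(self, image: np.ndarray) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedec2(
                image, self.wavelet, mode="periodization", level=self.levels
            )
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr.ravel()

    def _inverse_real(self, flat: np.ndarray) -> np.ndarray:
        arr = flat.reshape(self.image_shape)
        coeffs = pywt.array_to_coeffs(arr, self._slices, output_format="wavedec2")
        return pywt.waverec2(coeffs, self.wavelet, mode="periodization")

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Flat coefficient vector ``Ψ x`` (length ``rows*cols``)."""
        image = np.asarray(image)
        if image.shape != self.image_shape:
            raise ValueError(
                f"expected image of shape {self.image_shape}, got {image.shape}"
            )
        if np.iscomplexobj(image):
            return (self._forward_real(image.real)
                    + 1j * self._forward_real(image.imag))
        return self._forward_real(image)

    def adjoint(self, coeffs: np.ndarray) -> np.ndarray:
        """``Ψᵀ v = Ψ⁻¹ v`` (orthonormal transform)."""
        coeffs = np.asarray(coeffs)
        if coeffs.shape != (self.coeff_length,):
            raise ValueError(
                f"expected {self.coeff_length} coefficients, got {coeffs.shape}"
            )
        if np.iscomplexobj(coeffs):
            return (self._inverse_real(coeffs.real)
                    + 1j * self._inverse_real(coeffs.imag))
        return self._inverse_real(coeffs)

    # alias so both operator families share a surface
    apply = forward


def wavelet_transform(
    image: np.ndarray, wavelet: str = "db4", levels: int = 4
) -> np.ndarray:
    """One-shot orthonormal wavelet decomposition of a 2-D image."""
    op = WaveletOperator(np.asarray(image).shape, wavelet, levels)
    return op.forward(image)


def wavelet_adjoint(
    coeffs: np.ndarray,
    image_shape: Tuple[int, int],
    wavelet: str = "db4",
    levels: int = 4,
) -> np.ndarray:
    """Inverse (= adjoint) of :func:`wavelet_transform`."""
    op = WaveletOperator(image_shape, wavelet, levels)
    return op.adjoint(coeffs)


#: generic name for the default analysis operator family
AnalysisOperator = FiniteDifferenceOperator
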