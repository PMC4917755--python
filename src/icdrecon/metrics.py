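"""Reconstruction quality metrics: RLNE, HFEN and SSIM.

All three operate on magnitude images, so complex reconstructions are
compared up to a global phase.

* RLNE (relative ℓ2-norm error): ``‖|x_r| − |x_g|‖₂ / ‖|x_g|‖₂``.
* HFEN (high-frequency error norm): the same ratio after filtering both
  images with a 15×15 rotationally symmetric Laplacian-of-Gaussian kernel
  of standard deviation 1.5 pixels (symmetric boundary padding), which
  emphasizes edges and fine texture.
* SSIM: windowed structural similarity (11×11 Gaussian window, σ = 1.5,
  ``C1 = (0.01 L)²``, ``C2 = (0.03 L)²`` with dynamic range ``L = 1`` for
  max-1-normalized images); delegates to scikit-image, whose defaults with
  Gaussian weighting are exactly this configuration.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve
from skimage.metrics import structural_similarity

__all__ = ["rlne", "hfen", "ssim", "log_kernel"]


def _magnitudes(recon: np.ndarray, truth: np.ndarray):
    recon = np.abs(np.asarray(recon, dtype=complex))
    truth = np.abs(np.asarray(truth, dtype=complex))
    if recon.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: recon {recon.shape} vs truth {truth.shape}"
        )
    return recon, truth


def rlne(recon: np.ndarray, truth: np.ndarray) -> float:
    """Relative ℓ2-norm error between magnitude images."""
    recon, truth = _magnitudes(recon, truth)
    denom = np.linalg.norm(truth)
    if denom == 0:
        raise ZeroDivisionError("ground truth is identically zero")
    return float(np.linalg.norm(recon - truth) / denom)


def log_kernel(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Rotationally symmetric Laplacian-of-Gaussian kernel, zero-sum.

    Constructed like the classical image-processing ``log`` filter: a
    Gaussian of the given σ truncated to ``size × size``, composed with the
    Laplacian, normalized so the Gaussian sums to one and shifted to exact
    zero total weight.
    """
    if size % 2 != 1 or size < 3:
        raise ValueError("size must be an odd integer >= 3")
    half = size // 2
    grid = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(grid, grid)
    r2 = xx**2 + yy**2
    gauss = np.exp(-r2 / (2.0 * sigma**2))
    gauss /= gauss.sum()
    kernel = gauss * (r2 - 2.0 * sigma**2) / sigma**4
    return kernel - kernel.mean()


_LOG_KERNEL = log_kernel()


def hfen(recon: np.ndarray, truth: np.ndarray) -> float:
    """High-frequency error norm with the 15×15, σ=1.5 LoG filter."""
    recon, truth = _magnitudes(recon, truth)
    filt_truth = convolve(truth, _LOG_KERNEL, mode="reflect")
    denom = np.linalg.norm(filt_truth)
    # a constant truth leaves only rounding noise after the zero-sum kernel
    if denom <= 1e-12 * max(np.linalg.norm(truth), 1e-300):
        raise ZeroDivisionError(
            "LoG of the ground truth is identically zero (constant image)"
        )
    filt_recon = convolve(recon, _LOG_KERNEL, mode="reflect")
    return float(np.linalg.norm(filt_recon - filt_truth) / denom)


def ssim(recon: np.ndarray, truth: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity index over 11×11 Gaussian windows."""
    recon, truth = _magnitudes(recon, truth)
    if min(recon.shape) < 11:
        raise ValueError(
            f"image sides {recon.shape} are smaller than the 11x11 SSIM window"
        )
    return float(
        structural_similarity(
            truth,
            recon,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )
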