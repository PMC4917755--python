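"""Image, mask and report I/O for the command-line tools.

Two interchange forms are supported for images:

* PNG — 8- or 16-bit grayscale of the magnitude (scaled to the full bit
  range of the stated maximum, 1.0 by default);
* a raw array container — a ``.npy`` payload next to a ``.json`` header
  recording shape, dtype and whether the array is complex, which preserves
  complex images losslessly.

Masks serialize to 0/255 PNG plus a JSON metadata sidecar (scheme, seed,
realized sampling ratio).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image as PILImage

from .sampling import SamplingMask

__all__ = [
    "save_image_png",
    "load_image_png",
    "save_array",
    "load_array",
    "save_mask",
    "load_mask",
    "save_json",
]

PathLike = Union[str, Path]


def save_image_png(
    path: PathLike, image: np.ndarray, bit_depth: int = 16, vmax: float = 1.0
) -> None:
    """Write the magnitude of ``image`` as an 8/16-bit grayscale PNG."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    mag = np.abs(np.asarray(image, dtype=complex)).real
    top = (1 << bit_depth) - 1
    scaled = np.clip(mag / vmax, 0.0, 1.0) * top
    if bit_depth == 8:
        PILImage.fromarray(scaled.astype(np.uint8)).save(path)
    else:
        PILImage.fromarray(scaled.astype(np.uint16)).save(path)


def load_image_png(path: PathLike, vmax: float = 1.0) -> np.ndarray:
    """Read a grayscale PNG back to floats in ``[0, vmax]``."""
    img = PILImage.open(path)
    arr = np.asarray(img, dtype=float)
    top = 255.0 if arr.max() <= 255 and img.mode in ("L", "P") else 65535.0
    return arr / top * vmax


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_array(path: PathLike, array: np.ndarray, extra: dict | None = None) -> None:
    """Raw array container: ``.npy`` payload + JSON header sidecar."""
    path = Path(path)
    array = np.asarray(array)
    np.save(path.with_suffix(".npy"), array)
    header = {
        "shape": list(array.shape),
        "dtype": str(array.dtype),
        "complex": bool(np.iscomplexobj(array)),
    }
    if extra:
        header.update(extra)
    _sidecar(path).write_text(json.dumps(header, indent=2, default=float))


def load_array(path: PathLike) -> np.ndarray:
    path = Path(path)
    return np.load(path.with_suffix(".npy"))


def save_mask(path: PathLike, mask: SamplingMask) -> None:
    """Mask as 0/255 PNG (centered frame, for inspection) + JSON sidecar.

    The PNG shows the centered-frequency frame; the sidecar records that
    the stored array layout is FFT-native, plus scheme/seed/ratio metadata.
    """
    path = Path(path)
    PILImage.fromarray(
        (mask.centered().astype(np.uint8)) * 255, mode="L"
    ).save(path.with_suffix(".png"))
    np.save(path.with_suffix(".npy"), mask.array)
    meta = mask.metadata()
    meta["layout"] = "fft-native (DC at [0,0]); PNG shown centered"
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=float))


def load_mask(path: PathLike) -> SamplingMask:
    path = Path(path)
    arr = np.load(path.with_suffix(".npy"))
    meta = json.loads(_sidecar(path).read_text())
    return SamplingMask(arr, scheme=meta.get("scheme", "loaded"),
                        params=meta.get("params", {}))


def save_json(path: PathLike, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
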