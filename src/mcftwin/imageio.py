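"""Grayscale image I/O: PNG/TIFF, 8/16-bit, normalized to float in [0, 1]."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float64 in [0, 1] (rescaled by dtype range)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
        return np.clip(arr / _dtype_max(np.uint8 if arr.max() <= 255 else np.uint16), 0, 1)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / _dtype_max(arr.dtype)
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray, bitdepth: int = 16) -> None:
    """Write a float [0, 1] image as 8/16-bit grayscale PNG or TIFF."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bitdepth == 16:
        q = np.round(img * 65535).astype(np.uint16)
    elif bitdepth == 8:
        q = np.round(img * 255).astype(np.uint8)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    else:
        if bitdepth == 16:
            Image.fromarray(q, mode="I;16").save(path)
        else:
            Image.fromarray(q, mode="L").save(path)


def _dtype_max(dtype) -> float:
    return float(np.iinfo(dtype).max)
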