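"""Grayscale image file I/O (PNG and TIFF).

Images live in memory as plain 2-D float64 arrays together with a declared
dynamic range ``L`` (1.0 for float data, 255 for 8-bit).  Values are clipped
to ``[0, L]`` only at write time.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_image", "write_image"]


def read_image(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a grayscale PNG or TIFF; returns ``(pixels, dynamic_range)``.

    8-bit files map to ``L = 255``, 16-bit to ``L = 65535``, float TIFF to
    ``L = 1.0``.  RGB/multi-channel files are rejected rather than silently
    converted, since a color-to-gray convention would change every metric.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel grayscale image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        dynamic_range = 255.0
    elif arr.dtype == np.uint16:
        dynamic_range = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        dynamic_range = 1.0
    else:
        raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}")
    return arr.astype(np.float64), dynamic_range


def write_image(path: str | Path, img: np.ndarray, dynamic_range: float = 1.0) -> None:
    """Write ``img`` clipped to ``[0, dynamic_range]``.

    ``.png`` files are written as 8-bit (rescaled from the dynamic range);
    ``.tif``/``.tiff`` as 32-bit float, clipped but not rescaled.
    """
    path = Path(path)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("only single-channel 2-D images can be written")
    clipped = np.clip(arr, 0.0, dynamic_range)
    suffix = path.suffix.lower()
    if suffix == ".png":
        scaled = np.round(clipped / dynamic_range * 255.0).astype(np.uint8)
        iio.imwrite(path, scaled)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, clipped.astype(np.float32))
    else:
        raise ValueError(f"unsupported image format '{suffix}' (use .png or .tiff)")
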