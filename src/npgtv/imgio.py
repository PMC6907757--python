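"""Reading and writing grayscale images as unit-range float arrays.

8- and 16-bit PNG and TIFF are supported. On read, integer samples are
mapped to [0, 1] by dividing by the bit-depth maximum; RGB(A) input is
converted to luminance (Rec. 601 weights) with a logged warning. On write,
unit-range intensities are quantized with round-half-up at the requested
depth.
"""

from __future__ import annotations

import logging
import os

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "ImageIOError"]

logger = logging.getLogger(__name__)

_SUPPORTED_EXT = (".png", ".tif", ".tiff")
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageIOError(IOError):
    """Unreadable, unwritable or unsupported image file."""


def _check_extension(path) -> None:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise ImageIOError(
            f"unsupported image format {ext!r}; supported formats: {', '.join(_SUPPORTED_EXT)}"
        )


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image into a float array in [0, 1]."""
    _check_extension(path)
    if not os.path.exists(path):
        raise ImageIOError(f"image file not found: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises plugin-specific errors
        raise ImageIOError(f"could not read {path}: {exc}") from exc

    if raw.ndim == 3:
        if raw.shape[2] == 4:
            raw = raw[:, :, :3]
        logger.warning("%s is multi-channel; converting to luminance", path)
        raw = raw.astype(float) @ _LUMA
        arr = raw
        maxval = 255.0 if raw.max() > 1.0 else 1.0
    elif raw.ndim == 2:
        arr = raw.astype(float)
        if raw.dtype == np.uint8:
            maxval = 255.0
        elif raw.dtype == np.uint16:
            maxval = 65535.0
        else:
            maxval = float(max(arr.max(), 1.0))
    else:
        raise ImageIOError(f"expected a 2-D image, got shape {raw.shape}")

    return np.clip(arr / maxval, 0.0, 1.0)


def write_image(image: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write a unit-range image as PNG/TIFF at 8 or 16 bits (round-half-up)."""
    _check_extension(path)
    if bit_depth not in (8, 16):
        raise ImageIOError(f"bit_depth must be 8 or 16, got {bit_depth}")
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ImageIOError(f"expected a 2-D image, got shape {arr.shape}")
    maxval = 2**bit_depth - 1
    quant = np.floor(np.clip(arr, 0.0, 1.0) * maxval + 0.5)
    data = quant.astype(np.uint8 if bit_depth == 8 else np.uint16)
    try:
        iio.imwrite(path, data)
    except Exception as exc:
        raise ImageIOError(f"could not write {path}: {exc}") from exc
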