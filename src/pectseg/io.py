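"""Reading and writing mammogram rasters.

Supported formats: PGM (ASCII ``P2`` and binary ``P5``, maxval up to 65535)
and grayscale PNG (8 or 16 bit).  16-bit inputs are linearly min-max rescaled
to [0, 255] — MIAS-era film scans are 8-bit, and deeper inputs should degrade
gracefully rather than be refused.  Binary masks are written as 0/255
single-channel rasters.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import PectsegError, UnsupportedFormatError
from .types import GrayImage, as_mask

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.floor(255.0 * (arr - lo) / (hi - lo) + 0.5).astype(np.uint8)


def read_image(path) -> GrayImage:
    """Read a PGM/PNG frame as an 8-bit grayscale :class:`GrayImage`.

    Multi-frame containers are rejected; RGB(A) inputs are converted to
    luminance; >8-bit inputs are min-max rescaled to [0, 255].
    """
    try:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise UnsupportedFormatError(f"{path}: multi-frame input not supported")
            if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                arr = np.asarray(im, dtype=np.float64)
            elif im.mode == "L":
                arr = np.asarray(im)
            else:
                arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise PectsegError(f"cannot read image {path!r}: {exc}") from exc
    return GrayImage(_to_uint8(np.asarray(arr)), source_id=os.path.basename(str(path)))


def write_image(image, path) -> None:
    """Write an 8-bit grayscale raster as PGM (binary P5) or PNG by extension."""
    from .types import as_pixels

    arr = as_pixels(image)
    try:
        Image.fromarray(arr, mode="L").save(path)
    except (OSError, ValueError) as exc:
        raise PectsegError(f"cannot write image {path!r}: {exc}") from exc


def write_mask(mask, path) -> None:
    """Write a {0,1} mask as a 0/255 single-channel PNG or PGM file."""
    arr = as_mask(mask) * np.uint8(255)
    try:
        Image.fromarray(arr, mode="L").save(path)
    except (OSError, ValueError) as exc:
        raise PectsegError(f"cannot write mask {path!r}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a mask written by :func:`write_mask`; intensities > 128 are foreground."""
    return (read_image(path).pixels > 128).astype(np.uint8)
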