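"""Shared domain types.

Coordinates are 0-based ``(row, column)`` with row 0 at the top of the frame;
every angle and "upper half" rule in the package uses this convention.
Processing functions operate on plain ``numpy`` arrays (uint8 images, {0,1}
masks); :class:`GrayImage` is the thin container used at I/O and pipeline
boundaries where a source identifier travels with the pixels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


class Laterality(enum.Enum):
    """Side of the frame that holds the pectoral muscle wedge.

    ``MUSCLE_UPPER_LEFT`` corresponds to the RMLO view as digitised in
    MIAS-style data, ``MUSCLE_UPPER_RIGHT`` to the LMLO view.
    """

    MUSCLE_UPPER_LEFT = "left"
    MUSCLE_UPPER_RIGHT = "right"

    @property
    def mirrored(self) -> "Laterality":
        if self is Laterality.MUSCLE_UPPER_LEFT:
            return Laterality.MUSCLE_UPPER_RIGHT
        return Laterality.MUSCLE_UPPER_LEFT


@dataclass
class GrayImage:
    """2-D 8-bit intensity raster plus provenance.

    ``pixels`` is always stored as ``uint8``; constructing from any other
    dtype requires values already within [0, 255].
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ParameterError("GrayImage requires a non-empty 2-D array")
        if arr.dtype != np.uint8:
            if arr.size and (arr.min() < 0 or arr.max() > 255):
                raise ParameterError("intensities must lie in [0, 255]")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ParameterError("intensities must be integers")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def as_pixels(image) -> np.ndarray:
    """Coerce a GrayImage or array-like into a validated uint8 array."""
    if isinstance(image, GrayImage):
        return image.pixels
    return GrayImage(np.asarray(image)).pixels


def as_mask(mask) -> np.ndarray:
    """Coerce array-like into a {0,1} uint8 mask."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ParameterError("mask must be 2-D")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ParameterError("mask values restricted to {0, 1}")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class BreastScene:
    """A cropped, enhanced frame plus its derived breast geometry."""

    image: GrayImage
    breast_mask: np.ndarray
    laterality: Laterality
    crop_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.crop_offset[0] < 0 or self.crop_offset[1] < 0:
            raise ParameterError("crop_offset components must be >= 0")
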