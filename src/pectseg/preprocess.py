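"""Frame clean-up and contrast enhancement ahead of edge detection.

Scanned-film MLO frames carry blank digitisation margins, film-label
artifacts, and poor soft-tissue contrast.  This module removes the margins
with a column-sum line profile, isolates the breast as the largest
thresholded component, infers which side holds the pectoral muscle, windows
the intensities inside the breast, applies contrast-limited adaptive
histogram equalization (CLAHE), and median-denoises the result.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .edges import otsu_threshold
from .errors import (
    ConstantRegionError,
    DegenerateThresholdError,
    EmptyContentError,
    ParameterError,
    UnresolvedLateralityError,
)
from .types import Laterality, as_mask, as_pixels

__all__ = [
    "remove_blank_margins",
    "segment_breast",
    "remove_artifacts",
    "detect_laterality",
    "window_breast",
    "clahe",
    "median_denoise",
]

_EIGHT = np.ones((3, 3), dtype=bool)


def remove_blank_margins(image, floor_fraction: float = 0.02):
    """Crop the blank left/right digitisation margins.

    The column-sum line profile is thresholded at ``noise floor +
    floor_fraction * profile range``, where the noise floor is the median of
    the 10 lowest column sums.  A column counts as blank only when it also
    falls below half the median column mass — the "rapidly changing point"
    exists only where a genuinely empty plateau meets content, so a frame
    whose columns all carry tissue is returned unchanged.  Columns outside
    the first/last non-blank column are removed; rows are never cropped.

    Returns ``(cropped_pixels, (0, left_columns_removed))``.
    """
    arr = as_pixels(image)
    if arr.max() == 0:
        raise EmptyContentError("blank image: column profile has no content")
    profile = arr.sum(axis=0, dtype=np.int64).astype(np.float64)
    k = min(10, profile.size)
    floor = float(np.median(np.sort(profile)[:k]))
    thr = floor + floor_fraction * (profile.max() - profile.min())
    blank = (profile < thr) & (profile < 0.5 * np.median(profile))
    keep = np.flatnonzero(~blank)
    if keep.size == 0:
        raise EmptyContentError("column profile entirely below the noise floor")
    left, right = int(keep[0]), int(keep[-1])
    return arr[:, left : right + 1], (0, left)


def segment_breast(image, bin_threshold: int | None = None) -> np.ndarray:
    """Binarize the frame into breast foreground vs. background.

    The threshold is taken from the full-frame histogram (Otsu) unless given
    explicitly; the foreground is then closed (3×3, one pass) and hole-filled.
    A constant frame degenerates to an all-foreground mask so downstream
    stages can report a structured failure instead of crashing here.
    """
    arr = as_pixels(image)
    if bin_threshold is None:
        try:
            bin_threshold = otsu_threshold(arr)
        except DegenerateThresholdError:
            return np.ones(arr.shape, dtype=np.uint8)
    fg = arr > bin_threshold
    # closing by hand: dilation pads with background, erosion with foreground,
    # so breast pixels on the frame border are not shaved off
    fg = ndi.binary_dilation(fg, structure=_EIGHT)
    fg = ndi.binary_erosion(fg, structure=_EIGHT, border_value=1)
    fg = ndi.binary_fill_holes(fg)
    return fg.astype(np.uint8)


def remove_artifacts(mask) -> np.ndarray:
    """Keep only the largest 8-connected component (the breast).

    Film labels and scanner artifacts are smaller disconnected regions.
    Equal-area ties go to the component whose first pixel comes earliest in
    row-major order (the labelling scan order).
    """
    m = as_mask(mask)
    labels, n = ndi.label(m, structure=_EIGHT)
    if n == 0:
        raise EmptyContentError("mask has no foreground component")
    areas = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(areas)) + 1  # argmax returns the first (lowest label) max
    return (labels == keep).astype(np.uint8)


def detect_laterality(scene_image, breast_mask) -> Laterality:
    """Infer the muscle side from where the breast mass sits.

    MIAS-style cases are single frames without view metadata; the chest wall
    (and hence the muscle) is on the side holding more breast-mask mass.  The
    centre column of an odd-width frame is excluded so the rule commutes with
    horizontal mirroring.
    """
    m = as_mask(breast_mask)
    if m.sum() == 0:
        raise EmptyContentError("empty breast mask")
    w = m.shape[1]
    centre = (w - 1) / 2.0
    cols = np.arange(w)
    left = int(m[:, cols < centre].sum())
    right = int(m[:, cols > centre].sum())
    if left == right:
        raise UnresolvedLateralityError(
            "breast mass split exactly equal; pass the orientation explicitly"
        )
    return Laterality.MUSCLE_UPPER_LEFT if left > right else Laterality.MUSCLE_UPPER_RIGHT


def window_breast(image, breast_mask) -> np.ndarray:
    """Stretch the in-breast intensity range [min, max] linearly to [0, 255].

    Pixels outside the breast mask are set to 0.
    """
    arr = as_pixels(image)
    m = as_mask(breast_mask).astype(bool)
    if not m.any():
        raise EmptyContentError("empty breast mask")
    vals = arr[m]
    lo, hi = int(vals.min()), int(vals.max())
    if lo == hi:
        raise ConstantRegionError("breast region is constant; window undefined")
    out = np.zeros(arr.shape, dtype=np.uint8)
    scaled = np.floor(255.0 * (arr[m].astype(np.float64) - lo) / (hi - lo) + 0.5)
    out[m] = np.clip(scaled, 0, 255).astype(np.uint8)
    return out


def _tile_edges(size: int, tiles: int) -> np.ndarray:
    return np.linspace(0, size, tiles + 1).round().astype(int)


def _clipped_mapping(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """256-entry equalization LUT for one tile with histogram clipping.

    Bins are capped at ``clip_limit`` × (tile pixel count); the clipped excess
    is redistributed uniformly over all 256 bins before the cumulative mapping
    ``v -> round(255 * cdf(v) / N)`` is formed.
    """
    n = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) == 1:
        return np.arange(256, dtype=np.float64)  # one-bin histogram: identity
    cap = clip_limit * n
    excess = np.maximum(hist - cap, 0.0).sum()
    if excess > 0:
        hist = np.minimum(hist, cap) + excess / 256.0
    cdf = np.cumsum(hist)
    return np.floor(255.0 * cdf / n + 0.5)


def clahe(image, clip_limit: float = 0.01, blocks: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The frame is divided into ``blocks`` tiles; each tile is equalized
    independently from its clipped 256-bin histogram, and per-pixel output is
    the bilinear blend of the four surrounding tile mappings (pixels outside
    the outer tile centres clamp to the nearest tile).  ``clip_limit`` is the
    per-bin cap as a fraction of the tile pixel count; values ≥ 1 disable
    clipping, so a 1×1 tiling then reduces to global histogram equalization.
    """
    arr = as_pixels(image)
    try:
        tr, tc = int(blocks[0]), int(blocks[1])
    except (TypeError, IndexError) as exc:
        raise ParameterError("blocks must be a (rows, cols) pair") from exc
    if tr < 1 or tc < 1 or clip_limit <= 0:
        raise ParameterError("blocks must be >= (1,1) and clip_limit > 0")
    h, w = arr.shape
    if h < tr or w < tc:
        raise ParameterError("image smaller than the tile grid")

    redges = _tile_edges(h, tr)
    cedges = _tile_edges(w, tc)
    maps = np.empty((tr, tc, 256), dtype=np.float64)
    rc = np.empty(tr)
    cc = np.empty(tc)
    for i in range(tr):
        rc[i] = (redges[i] + redges[i + 1] - 1) / 2.0
        for j in range(tc):
            cc[j] = (cedges[j] + cedges[j + 1] - 1) / 2.0
            tile = arr[redges[i] : redges[i + 1], cedges[j] : cedges[j + 1]]
            maps[i, j] = _clipped_mapping(tile, clip_limit)

    def _axis_weights(coords: np.ndarray, centres: np.ndarray):
        i0 = np.clip(np.searchsorted(centres, coords, side="right") - 1, 0, len(centres) - 1)
        i1 = np.minimum(i0 + 1, len(centres) - 1)
        span = centres[i1] - centres[i0]
        frac = np.where(span > 0, (coords - centres[i0]) / np.where(span > 0, span, 1), 0.0)
        return i0, i1, np.clip(frac, 0.0, 1.0)

    r0, r1, fr = _axis_weights(np.arange(h, dtype=np.float64), rc)
    c0, c1, fc = _axis_weights(np.arange(w, dtype=np.float64), cc)
    R0, R1 = r0[:, None], r1[:, None]
    C0, C1 = c0[None, :], c1[None, :]
    FR, FC = fr[:, None], fc[None, :]
    out = (
        (1 - FR) * (1 - FC) * maps[R0, C0, arr]
        + (1 - FR) * FC * maps[R0, C1, arr]
        + FR * (1 - FC) * maps[R1, C0, arr]
        + FR * FC * maps[R1, C1, arr]
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def median_denoise(image, window: int = 3) -> np.ndarray:
    """Median filter with a square ``window`` × ``window`` neighbourhood.

    Borders use edge-inclusive reflect padding.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("median window must be odd and >= 3")
    arr = as_pixels(image)
    return ndi.median_filter(arr, size=window, mode="reflect")
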