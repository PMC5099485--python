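"""Oblique edge detection with corner-distance weighting.

The pectoral boundary descends obliquely from the top chest-wall corner and,
on film, is *blurred*, while the main confounder — a folded-skin crease — is
sharp but sits farther from that corner.  The stage therefore combines a
diagonal compass-gradient kernel (optionally after light Gaussian smoothing,
which favours blurred boundaries) with a linear wedge of distance weights
anchored at the muscle corner, binarizes the weighted response with Otsu's
threshold, suppresses the breast skin line, and keeps candidate components
whose centroid lies in the upper half of the breast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    DegenerateThresholdError,
    EmptyContentError,
    NoCandidateError,
    ParameterError,
)
from .types import Laterality, as_mask, as_pixels

__all__ = [
    "ObliqueKernel",
    "EdgeCandidate",
    "make_oblique_kernel",
    "wedge_weights",
    "edge_map",
    "otsu_threshold",
    "suppress_skin_line",
    "select_candidates",
]

_EIGHT = np.ones((3, 3), dtype=bool)

# Diagonal compass gradient for a muscle in the upper-left corner: maximal
# response to an edge running upper-right -> lower-left with the bright side
# toward the top-left.
_LEFT_KERNEL = np.array([[2, 1, 0], [1, 0, -1], [0, -1, -2]], dtype=np.float64)


@dataclass(frozen=True)
class ObliqueKernel:
    """Zero-sum 3×3 oblique gradient kernel bound to the laterality it targets."""

    weights: np.ndarray
    orientation: Laterality

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if abs(w.sum()) > 1e-12:
            raise ParameterError("oblique kernel weights must sum to 0")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class EdgeCandidate:
    """One labelled connected region of the binarized edge map."""

    label: int
    pixels: np.ndarray  # (N, 2) array of (row, col)
    centroid: tuple[float, float]
    area: int


def make_oblique_kernel(orientation: Laterality, override=None) -> ObliqueKernel:
    """Build the oblique kernel for one laterality.

    The upper-right kernel is the column-mirror of the upper-left one with
    signs flipped, so a mirrored image yields a mirrored (absolute) response.
    ``override`` replaces the upper-left literal (it is mirrored the same way).
    """
    base = _LEFT_KERNEL if override is None else np.asarray(override, dtype=np.float64)
    if orientation is Laterality.MUSCLE_UPPER_LEFT:
        return ObliqueKernel(base.copy(), orientation)
    return ObliqueKernel(-base[:, ::-1].copy(), orientation)


def wedge_weights(height: int, width: int, orientation: Laterality) -> np.ndarray:
    """Linear-wedge distance weights anchored at the muscle corner.

    ``w(r, c) = max(0, 1 - d(r, c) / D)`` with ``d`` the Euclidean distance
    from the anchor corner pixel ((0,0) or (0, width-1)) and ``D`` the
    distance to the diagonally opposite corner.  A 1×1 frame gets weight 1.
    """
    if height < 1 or width < 1:
        raise ParameterError("height and width must be >= 1")
    rr, cc = np.mgrid[0:height, 0:width].astype(np.float64)
    anchor_c = 0.0 if orientation is Laterality.MUSCLE_UPPER_LEFT else float(width - 1)
    d = np.hypot(rr, cc - anchor_c)
    D = float(np.hypot(height - 1, width - 1))
    if D == 0.0:
        return np.ones((height, width), dtype=np.float64)
    return np.clip(1.0 - d / D, 0.0, 1.0)


def edge_map(image, kernel: ObliqueKernel, wedge: np.ndarray, presmooth_sigma: float = 0.0) -> np.ndarray:
    """Distance-weighted oblique edge response, rescaled to [0, 255].

    The image is (optionally) Gaussian-smoothed, convolved with the kernel
    under reflect padding, the absolute response is multiplied pixelwise by
    the wedge weights, and the result is linearly rescaled so its maximum
    maps to 255 (an all-zero response stays all-zero).
    """
    arr = as_pixels(image).astype(np.float64)
    wedge = np.asarray(wedge, dtype=np.float64)
    if wedge.shape != arr.shape:
        raise ParameterError("wedge shape must equal image shape")
    if presmooth_sigma > 0:
        arr = ndi.gaussian_filter(arr, sigma=presmooth_sigma, mode="reflect")
    resp = np.abs(ndi.convolve(arr, kernel.weights, mode="reflect")) * wedge
    peak = resp.max()
    if peak == 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.floor(255.0 * resp / peak + 0.5).astype(np.uint8)


def otsu_threshold(image) -> int:
    """Otsu's threshold over the 256-bin histogram, exact integer arithmetic.

    Returns the smallest ``t`` maximizing the between-class variance of the
    split (<= t, > t).  Cross-multiplied integer comparison makes the argmax
    (and its smallest-t tie-break) immune to floating-point rounding.
    """
    arr = as_pixels(image)
    hist = np.bincount(arr.ravel(), minlength=256)
    if np.count_nonzero(hist) < 2:
        raise DegenerateThresholdError("single-intensity image has no Otsu threshold")
    counts = [int(c) for c in hist]
    total = sum(counts)
    total_sum = sum(v * c for v, c in enumerate(counts))
    best_t, best_num, best_den = 0, -1, 1  # variance as exact fraction num/den
    w0 = s0 = 0
    for t in range(255):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        # between-class variance ∝ (s0*w1 - (total_sum-s0)*w0)^2 / (w0*w1)
        num = (s0 * w1 - (total_sum - s0) * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:  # strict: keeps the smallest argmax
            best_t, best_num, best_den = t, num, den
    return best_t


def suppress_skin_line(edge_mask, breast_mask, band: int = 5) -> np.ndarray:
    """Zero edge pixels within ``band`` px of the breast-mask boundary.

    The breast mask is eroded ``band`` times with a 3×3 structuring element
    (frame borders are not treated as boundary) and intersected with the edge
    mask, removing the skin-line response while keeping interior edges.
    """
    em = as_mask(edge_mask)
    bm = as_mask(breast_mask)
    if em.shape != bm.shape:
        raise ParameterError("edge mask and breast mask shapes differ")
    core = ndi.binary_erosion(bm, structure=_EIGHT, iterations=int(band), border_value=1)
    if not core.any():
        raise EmptyContentError("suppression band swallowed the whole breast")
    return (em.astype(bool) & core).astype(np.uint8)


def select_candidates(edge_mask, breast_top: int, breast_bottom: int, height_fraction: float = 0.5):
    """Label the edge mask and keep upper-breast candidate components.

    Components (8-connectivity) whose centroid row is below
    ``breast_top + height_fraction * (breast_bottom - breast_top)`` are
    discarded; survivors are returned sorted by area, largest first.
    """
    if breast_top >= breast_bottom:
        raise ParameterError("breast_top must be < breast_bottom")
    em = as_mask(edge_mask)
    labels, n = ndi.label(em, structure=_EIGHT)
    cutoff = breast_top + height_fraction * (breast_bottom - breast_top)
    out = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        centroid = (float(rows.mean()), float(cols.mean()))
        if centroid[0] < cutoff:
            out.append(
                EdgeCandidate(
                    label=lab,
                    pixels=np.column_stack([rows, cols]),
                    centroid=centroid,
                    area=int(rows.size),
                )
            )
    if not out:
        raise NoCandidateError("no edge component centred in the upper breast")
    out.sort(key=lambda c: (-c.area, c.label))
    return out
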