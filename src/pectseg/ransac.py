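"""Quadratic RANSAC fit of the pectoral boundary, and mask rasterisation.

The boundary is modelled as ``x = a·y² + b·y + c`` with ``y`` the row and
``x`` the column: the edge is near-vertical, so the column is single-valued
in the row.  The fit repeats ``K`` times: draw a minimal sample of ``n``
points, least-squares-fit the quadratic, and count points whose absolute
column residual is within ``eps``; the model with the largest consensus set
wins (ties: the earlier iteration).  A final least-squares refit on the full
inlier set polishes the winner (disable with ``refit=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitFailureError, InsufficientDataError, ParameterError
from .types import Laterality

__all__ = ["RansacConfig", "QuadraticCurve", "fit_quadratic_ransac", "curve_to_mask"]


@dataclass(frozen=True)
class RansacConfig:
    """Sampling parameters: minimal sample ``n`` (>= 3 for a quadratic),
    inlier tolerance ``eps`` in pixels, iteration cap ``K``, RNG ``seed``,
    and whether to polish the winner with a full-inlier refit."""

    n: int = 3
    eps: float = 3.0
    K: int = 1000
    seed: int = 0
    refit: bool = True

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ParameterError("quadratic fit needs a sample of n >= 3 points")
        if not self.eps > 0:
            raise ParameterError("eps must be > 0")
        if self.K < 1:
            raise ParameterError("K must be >= 1")


@dataclass(frozen=True)
class QuadraticCurve:
    """Fitted boundary ``x = a·y² + b·y + c`` with its consensus set."""

    a: float
    b: float
    c: float
    inliers: np.ndarray = field(repr=False)  # (M, 2) rows of (row, col)
    consensus: int = 0

    def x_at(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        return self.a * y * y + self.b * y + self.c

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def _lstsq_quadratic(rows: np.ndarray, cols: np.ndarray) -> np.ndarray | None:
    """Least-squares coefficients (a, b, c), or None for a singular design."""
    A = np.column_stack([rows * rows, rows, np.ones_like(rows)])
    coef, _, rank, _ = np.linalg.lstsq(A, cols, rcond=None)
    if rank < 3:
        return None
    return coef


def fit_quadratic_ransac(points, config: RansacConfig = RansacConfig()) -> QuadraticCurve:
    """RANSAC fit of ``x = a·y² + b·y + c`` to (row, col) points.

    Fully deterministic given ``config.seed``.  Raises
    :class:`InsufficientDataError` with fewer than ``n`` points or all rows
    identical, and :class:`FitFailureError` when no iteration reaches a
    consensus of at least ``n``.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (N, 2) array of (row, col)")
    N = pts.shape[0]
    if N < config.n:
        raise InsufficientDataError(f"need at least {config.n} points, got {N}")
    rows, cols = pts[:, 0], pts[:, 1]
    if np.unique(rows).size < 3:
        raise InsufficientDataError("points span fewer than 3 distinct rows")

    rng = np.random.default_rng(config.seed)
    design = np.column_stack([rows * rows, rows, np.ones(N)])
    best_coef = None
    best_consensus = -1
    for _ in range(config.K):
        idx = rng.choice(N, size=config.n, replace=False)
        coef = _lstsq_quadratic(rows[idx], cols[idx])
        if coef is None:
            continue
        resid = np.abs(design @ coef - cols)
        consensus = int((resid <= config.eps).sum())
        if consensus > best_consensus:  # strict: earlier iteration wins ties
            best_consensus = consensus
            best_coef = coef
    if best_coef is None or best_consensus < config.n:
        raise FitFailureError(
            f"best consensus {max(best_consensus, 0)} below minimal sample {config.n}"
        )

    inlier_idx = np.abs(design @ best_coef - cols) <= config.eps
    coef = best_coef
    if config.refit:
        polished = _lstsq_quadratic(rows[inlier_idx], cols[inlier_idx])
        if polished is not None:
            coef = polished
            inlier_idx = np.abs(design @ coef - cols) <= config.eps
    inliers = pts[inlier_idx]
    return QuadraticCurve(float(coef[0]), float(coef[1]), float(coef[2]),
                          inliers=inliers, consensus=int(inlier_idx.sum()))


def curve_to_mask(curve, height: int, width: int, orientation: Laterality) -> np.ndarray:
    """Rasterise the muscle side of a boundary curve into a {0,1} mask.

    Per row ``y`` the boundary column is ``xb = a·y² + b·y + c`` rounded
    half-up; boundary pixels belong to the mask.  Upper-left muscles occupy
    ``x <= xb``, upper-right ``x >= xb``.  Rows where the curve leaves the
    frame toward the muscle corner are full, rows where it leaves the other
    way are empty.

    ``curve`` may be a :class:`QuadraticCurve` or an ``(a, b, c)`` triple.
    """
    if height < 1 or width < 1:
        raise ParameterError("mask dimensions must be >= 1")
    a, b, c = curve.coefficients if isinstance(curve, QuadraticCurve) else curve
    y = np.arange(height, dtype=np.float64)
    xb = a * y * y + b * y + c
    xr = np.floor(np.clip(xb, -2.0, width + 1.0) + 0.5)  # clip before int cast
    cols = np.arange(width)[None, :]
    if orientation is Laterality.MUSCLE_UPPER_LEFT:
        return (cols <= xr[:, None]).astype(np.uint8)
    return (cols >= xr[:, None]).astype(np.uint8)
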