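"""Hough line detection, angle gating, and chain linking.

The binarized edge map of the pectoral boundary is usually fragmented.  A
probabilistic Hough transform recovers straight sub-segments, an angle gate
keeps only orientations a pectoral edge can have, segments with similar
angles and small endpoint gaps are linked into chains, and the longest chain
is taken as the muscle outline.

Angle convention (stated explicitly because it decides the gates): a
segment's directed angle is measured in degrees counterclockwise from the
+column axis with +row pointing *down*, in [0, 360).  Reversing a segment
adds 180°.  Inclusive gates: [100°, 170°] for ``MUSCLE_UPPER_RIGHT`` (LMLO)
and [280°, 350°] for ``MUSCLE_UPPER_LEFT`` (RMLO); the two ranges are
congruent mod 180, so only *directed* segments make them distinguishable —
:func:`gate_for_scene` orients (and, for the upper-right case, column-
mirrors) segments so a true pectoral edge of each laterality lands in its
own gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as draw_line
from skimage.transform import probabilistic_hough_line

from .errors import NoCandidateError, ParameterError
from .types import Laterality, as_mask

__all__ = [
    "LineSegment",
    "LineChain",
    "hough_segments",
    "gate_by_angle",
    "gate_for_scene",
    "connect_chains",
    "longest_chain",
]

GATES = {
    Laterality.MUSCLE_UPPER_RIGHT: (100.0, 170.0),
    Laterality.MUSCLE_UPPER_LEFT: (280.0, 350.0),
}


@dataclass(frozen=True)
class LineSegment:
    """A directed straight segment between two (row, col) endpoints."""

    p0: tuple[int, int]
    p1: tuple[int, int]
    support: int = 0

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ParameterError("degenerate segment: identical endpoints")

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def angle_deg(self) -> float:
        """Directed angle in [0, 360), CCW from +col with +row down."""
        dr = self.p1[0] - self.p0[0]
        dc = self.p1[1] - self.p0[1]
        return math.degrees(math.atan2(dr, dc)) % 360.0

    def reversed(self) -> "LineSegment":
        return LineSegment(self.p1, self.p0, self.support)

    def mirrored(self, width: int) -> "LineSegment":
        """Reflect about the vertical midline of a ``width``-column frame."""
        (r0, c0), (r1, c1) = self.p0, self.p1
        return LineSegment((r0, width - 1 - c0), (r1, width - 1 - c1), self.support)

    def raster(self) -> np.ndarray:
        rr, cc = draw_line(self.p0[0], self.p0[1], self.p1[0], self.p1[1])
        return np.column_stack([rr, cc])


@dataclass(frozen=True)
class LineChain:
    """A maximal group of mutually connectable segments.

    ``total_length`` is the sum of member lengths plus the bridged endpoint
    gaps (summed over a minimum spanning tree of the connection graph), so a
    chain is never shorter than its longest member.
    """

    segments: tuple[LineSegment, ...]
    total_length: float
    pixels: np.ndarray = field(repr=False)  # (N, 2) unique rasterized points

    @property
    def support(self) -> int:
        return int(sum(s.support for s in self.segments))


def hough_segments(edge_mask, vote_threshold: int = 30, min_length: int = 20,
                   max_gap: int = 5, seed: int = 0):
    """Detect straight segments with a progressive probabilistic Hough transform.

    θ is sampled over [0°, 180°) at 1° resolution.  Each returned segment is
    oriented to point downward (row increasing; ties broken toward increasing
    column) and carries as ``support`` the number of on-pixels it covers.
    """
    em = as_mask(edge_mask)
    if not em.any():
        return []
    theta = np.deg2rad(np.arange(0.0, 180.0))
    raw = probabilistic_hough_line(
        em.astype(bool),
        threshold=int(vote_threshold),
        line_length=int(min_length),
        line_gap=int(max_gap),
        theta=theta,
        rng=int(seed),
    )
    out = []
    for (c0, r0), (c1, r1) in raw:
        if (r0, c0) == (r1, c1):
            continue
        if (r0, c0) > (r1, c1):  # orient row-increasing, then col-increasing
            r0, c0, r1, c1 = r1, c1, r0, c0
        seg = LineSegment((int(r0), int(c0)), (int(r1), int(c1)))
        pts = seg.raster()
        support = int(em[pts[:, 0], pts[:, 1]].sum())
        out.append(LineSegment(seg.p0, seg.p1, support))
    return out


def gate_by_angle(segments, orientation: Laterality):
    """Keep segments whose directed angle lies in the laterality's gate.

    Inclusive bounds: [100°, 170°] for MUSCLE_UPPER_RIGHT, [280°, 350°] for
    MUSCLE_UPPER_LEFT.  Idempotent and order-preserving.
    """
    lo, hi = GATES[orientation]
    return [s for s in segments if lo <= s.angle_deg <= hi]


def gate_for_scene(segments, orientation: Laterality, width: int):
    """Angle-gate Hough segments of an actual scene, returning the originals.

    For an upper-left muscle the boundary descends toward the lower-left, so
    row-*decreasing* segments fall in [280°, 350°]; for an upper-right muscle
    the column-mirrored, row-increasing segments fall in [100°, 170°].  The
    gate itself is always :func:`gate_by_angle`; this wrapper only chooses the
    canonical orientation per laterality and maps the kept set back.
    """
    if orientation is Laterality.MUSCLE_UPPER_LEFT:
        views = [s.reversed() for s in segments]
    else:
        views = [s.mirrored(width) for s in segments]
    kept_views = set(id(v) for v in gate_by_angle(views, orientation))
    return [s for s, v in zip(segments, views) if id(v) in kept_views]


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _endpoint_gap(s: LineSegment, t: LineSegment) -> float:
    return min(
        math.hypot(p[0] - q[0], p[1] - q[1])
        for p in (s.p0, s.p1)
        for q in (t.p0, t.p1)
    )


def connect_chains(segments, angle_tol: float = 10.0, gap_tol: float = 20.0):
    """Link similarly angled, nearby segments into maximal chains.

    Two segments are directly connectable when their directed angles differ
    by at most ``angle_tol`` (circular) and their minimum endpoint distance is
    at most ``gap_tol``; chains are the transitive closure of that relation,
    so the output partitions the input.  Bridged gaps (minimum spanning tree
    over the connection graph, weighted by endpoint distance) count toward
    ``total_length``.
    """
    segments = list(segments)
    n = len(segments)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if _angle_diff(segments[i].angle_deg, segments[j].angle_deg) <= angle_tol:
                gap = _endpoint_gap(segments[i], segments[j])
                if gap <= gap_tol:
                    edges.append((gap, i, j))
                    parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    # Kruskal MST per group over the qualifying edges, for bridged-gap length
    bridged = {root: 0.0 for root in groups}
    mst_parent = list(range(n))

    def mfind(i):
        while mst_parent[i] != i:
            mst_parent[i] = mst_parent[mst_parent[i]]
            i = mst_parent[i]
        return i

    for gap, i, j in sorted(edges):
        ri, rj = mfind(i), mfind(j)
        if ri != rj:
            mst_parent[ri] = rj
            bridged[find(i)] += gap

    chains = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        idxs = sorted(groups[root], key=lambda i: (segments[i].p0, segments[i].p1))
        members = tuple(segments[i] for i in idxs)
        total = sum(s.length for s in members) + bridged[root]
        pts = np.unique(np.vstack([s.raster() for s in members]), axis=0)
        chains.append(LineChain(members, total, pts))
    return chains


def longest_chain(chains) -> LineChain:
    """The chain of maximal total length (ties: larger support, then first)."""
    chains = list(chains)
    if not chains:
        raise NoCandidateError("no line chains to choose from")
    best = chains[0]
    for ch in chains[1:]:
        if ch.total_length > best.total_length or (
            ch.total_length == best.total_length and ch.support > best.support
        ):
            best = ch
    return best
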