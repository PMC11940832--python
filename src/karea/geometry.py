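"""2D computational-geometry primitives for convex-hull clustering.

Conventions used throughout the package:

* Hull vertex rings are **clockwise**, starting at the lexicographically
  smallest vertex (smallest x, then smallest y).
* Degenerate inputs never raise: a single point yields a 1-vertex "ring",
  a collinear set a 2-vertex segment ring; both have area 0.
* Points lying exactly on a separating line (within a scaled tolerance)
  classify to side 1 — the closed "below or on the line" half-plane.
* Exact duplicate coordinates collapse to a single hull vertex (the lowest
  point index wins); the remaining duplicates are interior members.

Orientation tests use the cross product ``(b - a) x (p - a)`` instead of a
slope comparison, which removes the vertical-line singularity while giving
identical classifications for non-vertical lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

#: relative orientation tolerance; multiplied by the squared bounding-box
#: diagonal of the point set under consideration.
ORIENT_EPS = 1e-12


class GeometryError(ValueError):
    """Invalid geometric input (empty member set, coincident line points, ...)."""


class Point2D(NamedTuple):
    """A single 2D point with its stable index inside a :class:`PointSet`."""

    x: float
    y: float
    index: int


@dataclass(frozen=True)
class PointSet:
    """Ordered collection of N 2D points with optional per-point labels.

    Parameters
    ----------
    coords
        Array of shape ``(N, 2)`` with finite float coordinates.
    labels
        Optional array of length N with ground-truth category identifiers.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise GeometryError("coords must have shape (N, 2) with N >= 1")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (coords.shape[0],):
                raise GeometryError("labels must have exactly one entry per point")
            object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return int(self.coords.shape[0])

    def point(self, i: int) -> Point2D:
        return Point2D(float(self.coords[i, 0]), float(self.coords[i, 1]), int(i))


@dataclass(frozen=True)
class HullPolygon:
    """Convex hull of a member set: vertex ring P(C), interior P̄(C), area A(C).

    ``vertices`` holds point indices in clockwise ring order starting at the
    lexicographically smallest vertex; ``interior`` holds every member index
    that is not a ring vertex (including points on edges and duplicates of
    vertex coordinates).  ``area`` is 0 for rings with fewer than 3 vertices.
    """

    vertices: np.ndarray
    interior: np.ndarray
    area: float

    @property
    def members(self) -> np.ndarray:
        return np.concatenate([self.vertices, self.interior])


def _bbox_diag_sq(coords: np.ndarray) -> float:
    d = coords.max(axis=0) - coords.min(axis=0)
    return float(d @ d)


def _ring_area(ring_coords: np.ndarray) -> float:
    """Shoelace area ½·|Σ (x_i·y_{i+1} − y_i·x_{i+1})| of a closed vertex ring."""
    if len(ring_coords) < 3:
        return 0.0
    x = ring_coords[:, 0]
    y = ring_coords[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _monotone_chain(pts: np.ndarray, tol: float) -> list[int]:
    """Counter-clockwise hull ring of lexicographically sorted unique points.

    Returns positions into ``pts``.  Strictly convex: collinear boundary
    points (cross within ``tol``) are popped.  For fully collinear input the
    ring degenerates to the two extreme points.
    """

    n = len(pts)

    def cross(o: int, a: int, b: int) -> float:
        return (pts[a, 0] - pts[o, 0]) * (pts[b, 1] - pts[o, 1]) - (
            pts[a, 1] - pts[o, 1]
        ) * (pts[b, 0] - pts[o, 0])

    lower: list[int] = []
    for i in range(n):
        while len(lower) >= 2 and cross(lower[-2], lower[-1], i) <= tol:
            lower.pop()
        lower.append(i)
    upper: list[int] = []
    for i in range(n - 1, -1, -1):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], i) <= tol:
            upper.pop()
        upper.append(i)
    return lower[:-1] + upper[:-1]


def convex_hull(ps: PointSet, members: np.ndarray | None = None) -> HullPolygon:
    """Convex hull of a member index set, via a monotone-chain Graham scan.

    The vertex ring is clockwise and starts at the lexicographically smallest
    vertex.  Duplicate coordinates collapse to the lowest index; collinear
    sets yield a degenerate 2-vertex ring with area 0.

    Raises
    ------
    GeometryError
        If ``members`` is empty, contains duplicates, or is out of range.
    """

    if members is None:
        members = np.arange(ps.n)
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise GeometryError("empty member set")
    if members.min() < 0 or members.max() >= ps.n:
        raise GeometryError("member index out of range")
    members = np.sort(members)
    if members.size > 1 and np.any(members[1:] == members[:-1]):
        raise GeometryError("duplicate member indices")

    pts = ps.coords[members]
    uniq, first = np.unique(pts, axis=0, return_index=True)
    rep = members[first]  # lowest point index per unique coordinate

    if len(uniq) == 1:
        vertices = rep[:1]
    else:
        tol = ORIENT_EPS * _bbox_diag_sq(uniq)
        ring_ccw = _monotone_chain(uniq, tol)
        if len(ring_ccw) >= 3:
            ring = [ring_ccw[0]] + ring_ccw[1:][::-1]  # clockwise, keep start
        else:
            ring = ring_ccw
        vertices = rep[np.asarray(ring, dtype=int)]

    interior = np.setdiff1d(members, vertices)
    area = _ring_area(ps.coords[vertices])
    return HullPolygon(vertices=vertices, interior=interior, area=float(area))


def polygon_area(h: HullPolygon, ps: PointSet) -> float:
    """Shoelace area of a hull's vertex ring (0 for degenerate rings)."""
    return _ring_area(ps.coords[h.vertices])


def _canonical_line(a, b) -> tuple[float, float, float, float]:
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    if ax == bx and ay == by:
        raise GeometryError("line endpoints coincide")
    if (bx, by) < (ax, ay):  # lexicographic canonical direction
        ax, ay, bx, by = bx, by, ax, ay
    return ax, ay, bx, by


def side_of_line(p, a, b, scale_sq: float | None = None) -> int:
    """Classify point ``p`` against the line through ``a`` and ``b``.

    Returns 1 for the closed side (on the line, or below it for non-vertical
    lines — the "line value >= y_p" half-plane) and 2 for the strict opposite
    side.  ``p``, ``a``, ``b`` are (x, y) pairs or :class:`Point2D`.
    """

    ax, ay, bx, by = _canonical_line(a, b)
    px, py = float(p[0]), float(p[1])
    if scale_sq is None:
        pts = np.array([[ax, ay], [bx, by], [px, py]])
        scale_sq = _bbox_diag_sq(pts)
    cr = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    return 1 if cr <= ORIENT_EPS * scale_sq else 2


def split_by_line(
    ps: PointSet, members: np.ndarray, a_idx: int, b_idx: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bipartition ``members`` by the line through points ``a_idx`` and ``b_idx``.

    On-line points (within the scaled orientation tolerance), including the
    endpoints themselves, go to the first side.  The two returned index
    arrays are disjoint and their union is ``members``.
    """

    members = np.asarray(members, dtype=int)
    a_idx, b_idx = int(a_idx), int(b_idx)
    mset = set(members.tolist())
    if a_idx not in mset or b_idx not in mset:
        raise GeometryError("line endpoints must be members of the split set")
    ax, ay, bx, by = _canonical_line(ps.coords[a_idx], ps.coords[b_idx])
    pts = ps.coords[members]
    tol = ORIENT_EPS * _bbox_diag_sq(pts)
    cr = (bx - ax) * (pts[:, 1] - ay) - (by - ay) * (pts[:, 0] - ax)
    side1 = cr <= tol
    return members[side1], members[~side1]


def contains_point(ps: PointSet, h: HullPolygon, q) -> bool:
    """Boundary-inclusive test whether ``q`` lies inside hull ``h``."""

    V = ps.coords[h.vertices]
    qx, qy = float(q[0]), float(q[1])
    scale_sq = max(_bbox_diag_sq(np.vstack([V, [[qx, qy]]])), 1e-300)
    tol = ORIENT_EPS * scale_sq
    if len(V) == 1:
        return (qx - V[0, 0]) ** 2 + (qy - V[0, 1]) ** 2 <= tol
    if len(V) == 2:
        a, b = V
        cr = (b[0] - a[0]) * (qy - a[1]) - (b[1] - a[1]) * (qx - a[0])
        if abs(cr) > tol:
            return False
        t = (qx - a[0]) * (b[0] - a[0]) + (qy - a[1]) * (b[1] - a[1])
        return -tol <= t <= float((b - a) @ (b - a)) + tol
    # clockwise ring: interior points have non-positive cross at every edge
    for i in range(len(V)):
        a = V[i]
        b = V[(i + 1) % len(V)]
        cr = (b[0] - a[0]) * (qy - a[1]) - (b[1] - a[1]) * (qx - a[0])
        if cr > tol:
            return False
    return True
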