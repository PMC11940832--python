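"""Independent test oracles.

Everything here deliberately avoids the package's own code paths: hulls by
gift wrapping (Jarvis march) instead of a monotone chain, areas by fan
triangulation, line sides by direct slope comparison, NMI by dictionary
loops, K-center optima by exhaustive enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TOL_FACTOR = 1e-12


def _scale_sq(pts: np.ndarray) -> float:
    span = pts.max(axis=0) - pts.min(axis=0)
    return float(span @ span)


def giftwrap_ring(coords: np.ndarray) -> np.ndarray:
    """Ordered hull ring (coordinates) by gift wrapping; strict vertices only.

    Collinear input degenerates to the two extreme points; duplicates are
    dropped first.
    """

    P = np.unique(np.asarray(coords, dtype=float), axis=0)
    n = len(P)
    if n == 1:
        return P
    tol = TOL_FACTOR * _scale_sq(P)
    start = 0  # lexicographic minimum after unique-sort
    ring = [start]
    cur = start
    for _ in range(n + 1):
        d = P - P[cur]
        # C[q, j] = cross(d_q, d_j); q is the next vertex iff every j lies
        # on one fixed side of cur->q (ties resolved to the farthest q)
        C = d[:, 0][:, None] * d[:, 1][None, :] - d[:, 1][:, None] * d[:, 0][None, :]
        ok = (C >= -tol).all(axis=1)
        dist2 = (d**2).sum(axis=1)
        ok &= dist2 > tol
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            break
        nxt = int(cand[np.argmax(dist2[cand])])
        if nxt == start:
            break
        ring.append(nxt)
        cur = nxt
    else:  # pragma: no cover
        raise RuntimeError("gift wrapping failed to terminate")
    return P[ring]


def ring_area(ring_coords: np.ndarray) -> float:
    """Polygon area of an ordered ring by fan triangulation from vertex 0."""
    ring_coords = np.asarray(ring_coords, dtype=float)
    if len(ring_coords) < 3:
        return 0.0
    v0 = ring_coords[0]
    total = 0.0
    for i in range(1, len(ring_coords) - 1):
        u = ring_coords[i] - v0
        w = ring_coords[i + 1] - v0
        total += u[0] * w[1] - u[1] * w[0]
    return abs(total) / 2.0


def slope_side(p, a, b) -> int:
    """Direct slope-form classification (non-vertical lines only): side 1 iff
    the line's value at x_p is >= y_p."""
    m = (a[1] - b[1]) / (a[0] - b[0])
    y_line = m * p[0] + (a[1] - m * a[0])
    return 1 if y_line >= p[1] else 2


def brute_candidates(coords: np.ndarray, members: np.ndarray):
    """All valid hull-vertex-pair splits of a member set, recomputed from
    scratch: gift-wrap hull, direct side classification, fan areas.

    Returns (parent_area, dict mapping canonical coordinate pairs to delta).
    """

    pts = np.asarray(coords, dtype=float)[np.asarray(members, dtype=int)]
    ring = giftwrap_ring(pts)
    A = ring_area(ring)
    tol = TOL_FACTOR * _scale_sq(pts)
    out = {}
    verts = [tuple(v) for v in ring]
    for va, vb in itertools.combinations(verts, 2):
        a, b = (va, vb) if va <= vb else (vb, va)
        cr = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
        s1 = cr <= tol
        if s1.all() or (~s1).all():
            continue
        A1 = ring_area(giftwrap_ring(pts[s1]))
        A2 = ring_area(giftwrap_ring(pts[~s1]))
        out[(a, b)] = A - A1 - A2
    return A, out


def brute_best_delta(coords: np.ndarray, members: np.ndarray) -> float | None:
    """Exhaustive maximum area reduction over all valid hull-vertex splits."""
    _, cands = brute_candidates(coords, members)
    if not cands:
        return None
    return max(cands.values())


def brute_kcenter_optimum(coords: np.ndarray, k: int) -> float:
    """Optimal K-center objective by exhaustive center-subset enumeration."""
    X = np.asarray(coords, dtype=float)
    n = len(X)
    best = math.inf
    for centers in itertools.combinations(range(n), k):
        D = np.linalg.norm(X[:, None, :] - X[list(centers)][None, :, :], axis=2)
        obj = D.min(axis=1).max()
        best = min(best, obj)
    return float(best)


def nmi_direct(true_labels, pred_labels) -> float:
    """Term-by-term NMI: mutual information over the geometric mean of the
    entropies, natural logs, dictionaries and explicit loops."""

    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    n = len(true_labels)
    joint: dict = {}
    pt: dict = {}
    pp: dict = {}
    for t, p in zip(true_labels, pred_labels):
        joint[(t, p)] = joint.get((t, p), 0) + 1
        pt[t] = pt.get(t, 0) + 1
        pp[p] = pp.get(p, 0) + 1
    ht = -sum((c / n) * math.log(c / n) for c in pt.values())
    hp = -sum((c / n) * math.log(c / n) for c in pp.values())
    if ht <= 0 or hp <= 0:
        groups_t = {t: {i for i, x in enumerate(true_labels) if x == t} for t in pt}
        groups_p = {p: {i for i, x in enumerate(pred_labels) if x == p} for p in pp}
        same = set(map(frozenset, groups_t.values())) == set(
            map(frozenset, groups_p.values())
        )
        return 1.0 if same else 0.0
    mi = 0.0
    for (t, p), c in joint.items():
        mi += (c / n) * math.log(c * n / (pt[t] * pp[p]))
    return mi / math.sqrt(ht * hp)
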