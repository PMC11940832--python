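"""Center-based comparison clusterers: K-center, K-median, K-means.

Each algorithm optimises the objective named after it:

* K-center  — minimise the maximum point-to-assigned-center distance
  (farthest-first traversal, the classical 2-approximation);
* K-median  — minimise the summed Euclidean distance to centers
  (Lloyd-style alternation with geometric-median center updates);
* K-means   — minimise the summed squared distance to centers
  (Lloyd iterations from a k-means++ seeding).

All three are seed-deterministic and return 1-based labels plus the
algorithm's own objective value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .geometry import PointSet

MAX_OUTER_ITER = 300
WEISZFELD_TOL = 1e-8
WEISZFELD_MAX_ITER = 100


@dataclass
class BaselineResult:
    labels: np.ndarray  # 1..K
    centers: np.ndarray
    objective: float
    iterations: int
    seed: int | None
    objective_history: list[float] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _validate_k(k: int, n: int) -> None:
    if not 1 <= k <= n:
        raise ValueError(f"K={k} must be in [1, N={n}]")


def k_center(ps: PointSet, k: int, seed: int | None = None) -> BaselineResult:
    """Farthest-first traversal for the K-center objective.

    The first center is point index 0 by default (reproducible benchmarks);
    passing a seed draws it uniformly instead.  Each subsequent center is the
    point farthest from its nearest chosen center (ties to the lowest index).
    """

    X = ps.coords
    n = ps.n
    _validate_k(k, n)
    if seed is None:
        first = 0
    else:
        first = int(np.random.default_rng(seed).integers(n))
    center_idx = [first]
    d = np.linalg.norm(X - X[first], axis=1)
    while len(center_idx) < k:
        nxt = int(np.argmax(d))
        center_idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
    centers = X[center_idx].copy()
    D = cdist(X, centers)
    labels = D.argmin(axis=1)
    objective = float(D[np.arange(n), labels].max())
    return BaselineResult(
        labels=labels + 1,
        centers=centers,
        objective=objective,
        iterations=k,
        seed=seed,
    )


def geometric_median(pts: np.ndarray, tol: float = WEISZFELD_TOL,
                     max_iter: int = WEISZFELD_MAX_ITER) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iteration.

    Uses the Vardi–Zhang correction when the iterate lands on a data point,
    so coincidence with an input point is handled rather than diverging.
    """

    pts = np.asarray(pts, dtype=float)
    if len(pts) == 1:
        return pts[0].copy()
    scale = float(np.linalg.norm(pts.max(0) - pts.min(0))) + 1e-30
    c = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - c, axis=1)
        coincident = d < 1e-14 * scale
        m = int(coincident.sum())
        others = ~coincident
        if not others.any():
            return c
        w = 1.0 / d[others]
        T = (pts[others] * w[:, None]).sum(axis=0) / w.sum()
        if m == 0:
            c_new = T
        else:
            R = ((pts[others] - c) * (1.0 / d[others])[:, None]).sum(axis=0)
            r = float(np.linalg.norm(R))
            if r <= m:  # current point is the minimiser
                return c
            lam = m / r
            c_new = max(0.0, 1.0 - lam) * T + min(1.0, lam) * c
        if np.linalg.norm(c_new - c) <= tol * scale:
            return c_new
        c = c_new
    return c


def _coordinate_median(pts: np.ndarray) -> np.ndarray:
    return np.median(pts, axis=0)


def _lloyd(
    X: np.ndarray,
    k: int,
    seed: int,
    update_center,
    metric: str,
    objective_from_D,
) -> BaselineResult:
    n = len(X)
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    centers = centers.astype(float)
    notes: list[str] = []
    history: list[float] = []
    labels_prev = None
    it = 0
    for it in range(1, MAX_OUTER_ITER + 1):
        D = cdist(X, centers, metric=metric)
        labels = D.argmin(axis=1)
        # empty clusters: re-seed at the point farthest from that center
        for _ in range(k):
            empty = [j for j in range(k) if not np.any(labels == j)]
            if not empty:
                break
            for j in empty:
                far = int(np.argmax(np.linalg.norm(X - centers[j], axis=1)))
                centers[j] = X[far]
                notes.append(f"iteration {it}: re-seeded empty cluster {j + 1}")
            D = cdist(X, centers, metric=metric)
            labels = D.argmin(axis=1)
        history.append(float(objective_from_D(D, labels)))
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            break
        labels_prev = labels
        for j in range(k):
            centers[j] = update_center(X[labels == j])
    D = cdist(X, centers, metric=metric)
    labels = D.argmin(axis=1)
    objective = float(objective_from_D(D, labels))
    return BaselineResult(
        labels=labels + 1,
        centers=centers,
        objective=objective,
        iterations=it,
        seed=seed,
        objective_history=history,
        notes=notes,
    )


def k_median(
    ps: PointSet, k: int, seed: int = 0, center_update: str = "geometric"
) -> BaselineResult:
    """Lloyd-style alternation for the K-median objective (summed distances).

    Centers are updated to the geometric median of each cluster (the true
    planar minimiser of the objective); ``center_update="coordinate"`` uses
    the coordinate-wise median instead.
    """

    _validate_k(k, ps.n)
    if center_update == "geometric":
        update = geometric_median
    elif center_update == "coordinate":
        update = _coordinate_median
    else:
        raise ValueError("center_update must be 'geometric' or 'coordinate'")
    return _lloyd(
        ps.coords,
        k,
        seed,
        update,
        metric="euclidean",
        objective_from_D=lambda D, lab: D[np.arange(len(D)), lab].sum(),
    )


def k_means(ps: PointSet, k: int, seed: int = 0) -> BaselineResult:
    """Lloyd's algorithm for the K-means objective (summed squared distances),
    seeded by k-means++."""

    _validate_k(k, ps.n)
    return _lloyd(
        ps.coords,
        k,
        seed,
        lambda pts: pts.mean(axis=0),
        metric="sqeuclidean",
        objective_from_D=lambda D, lab: D[np.arange(len(D)), lab].sum(),
    )
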