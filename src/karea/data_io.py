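"""Point and expression-matrix I/O, the PCA front end, and the synthetic
fixture generator.

The generator plants cluster structure with a controlled *separation ratio*
(minimum inter-center distance divided by the maximum within-cluster radius)
so tests can construct regimes where splitting between clusters removes far
more hull area than splitting within one.  Shapes: isotropic Gaussian blobs,
uniform samples inside a random convex polygon, and exactly collinear sets.
Optional outliers are planted uniformly in an inflated bounding box and
carry the label of their nearest cluster center.  Hierarchical specs nest
the placement recursively and record the true group tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread
from sklearn.decomposition import PCA

from .geometry import PointSet, contains_point, convex_hull

# ---------------------------------------------------------------------------
# point CSV I/O


def read_points(path) -> PointSet:
    """Read a point set from CSV (columns x, y and optional label, by header
    or by position).  Row order becomes the point index."""

    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns (x, y)")
    cols = {str(c).lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        xcol, ycol = cols["x"], cols["y"]
        lcol = cols.get("label")
    else:
        xcol, ycol = df.columns[0], df.columns[1]
        lcol = df.columns[2] if df.shape[1] >= 3 else None
    x = pd.to_numeric(df[xcol], errors="coerce")
    y = pd.to_numeric(df[ycol], errors="coerce")
    bad = x.isna() | y.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: non-numeric coordinate at line {line}")
    labels = df[lcol].to_numpy() if lcol is not None else None
    return PointSet(np.column_stack([x.to_numpy(), y.to_numpy()]), labels)


def write_points(ps: PointSet, path, header_comments: list[str] | None = None) -> None:
    """Write a point set as CSV (x, y[, label]); full float precision so a
    read/write cycle is lossless."""

    path = Path(path)
    data = {"x": ps.coords[:, 0], "y": ps.coords[:, 1]}
    if ps.labels is not None:
        data["label"] = ps.labels
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        # %.17g round-trips any float64 exactly
        df.to_csv(fh, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# expression matrices


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense cells x genes matrix with id sidecars."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("expression matrix must be 2D and non-empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        if v.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("id lists do not match matrix dimensions")
        object.__setattr__(self, "values", v)


def _read_names(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    path,
    fmt: str | None = None,
    orientation: str = "cells-by-genes",
    row_names=None,
    col_names=None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV (row index + header) or MatrixMarket
    MTX with two sidecar name files.

    ``orientation`` declares what the rows of the *file* are; it is never
    guessed from the shape.  ``genes-by-cells`` input is transposed so the
    returned matrix is always cells x genes.
    """

    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix.lower() == ".mtx" else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        if df.empty:
            raise ValueError(f"{path}: empty expression matrix")
        values = df.to_numpy(dtype=float)
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
    elif fmt == "mtx":
        m = mmread(str(path))
        values = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
        if values.size == 0:
            raise ValueError(f"{path}: empty expression matrix")
        stem = path.with_suffix("")
        rows_path = Path(row_names) if row_names else Path(f"{stem}_rows.txt")
        cols_path = Path(col_names) if col_names else Path(f"{stem}_cols.txt")
        rows = _read_names(rows_path)
        cols = _read_names(cols_path)
        if len(rows) != values.shape[0] or len(cols) != values.shape[1]:
            raise ValueError(f"{path}: sidecar name counts do not match matrix shape")
    else:
        raise ValueError("fmt must be 'csv' or 'mtx'")

    if orientation == "genes-by-cells":
        values = values.T
        rows, cols = cols, rows
    elif orientation != "cells-by-genes":
        raise ValueError("orientation must be 'cells-by-genes' or 'genes-by-cells'")
    return ExpressionMatrix(values=values, cell_ids=rows, gene_ids=cols)


def embed_2d(m: ExpressionMatrix, transform: str = "log1p-cpm") -> PointSet:
    """Project an expression matrix to its top-2 principal components.

    ``log1p-cpm`` first normalises each cell to 10^4 total counts and applies
    log1p.  The decomposition is a deterministic full SVD; each component's
    sign is fixed so that its largest-magnitude gene loading is positive.
    """

    X = m.values
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    if transform == "log1p-cpm":
        lib = X.sum(axis=1)
        if np.any(lib <= 0):
            raise ValueError("cannot CPM-normalise a cell with zero total count")
        X = np.log1p(X / lib[:, None] * 1e4)
    elif transform != "none":
        raise ValueError("transform must be 'log1p-cpm' or 'none'")
    if not np.any(X - X.mean(axis=0)):
        raise ValueError("constant matrix: no variance to embed")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    for i in range(2):
        j = int(np.argmax(np.abs(pca.components_[i])))
        if pca.components_[i, j] < 0:
            scores[:, i] *= -1.0
    return PointSet(scores)


# ---------------------------------------------------------------------------
# synthetic fixtures


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted clustering.

    ``separation`` is the ratio of the minimum inter-center distance to the
    maximum within-cluster radius; 10 gives visually disjoint clusters whose
    between-cluster hull area dwarfs any within-cluster area.
    """

    n_clusters: int = 4
    points_per_cluster: int = 50
    shape: str = "gaussian"  # gaussian | convex-polygon | collinear
    separation: float = 10.0
    outlier_fraction: float = 0.0
    hierarchy_depth: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1 or self.points_per_cluster < 1:
            raise ValueError("counts must be >= 1")
        if self.n_clusters > 500:
            raise ValueError("infeasible spec: too many clusters to place")
        if self.shape not in ("gaussian", "convex-polygon", "collinear"):
            raise ValueError(f"unknown cluster shape {self.shape!r}")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.hierarchy_depth < 1:
            raise ValueError("hierarchy_depth must be >= 1")


@dataclass
class SyntheticData:
    """Generator output: labeled points, leaf-cluster centers, the true group
    hierarchy, and the indices of any planted outliers."""

    points: PointSet
    centers: np.ndarray
    hierarchy: dict
    outlier_indices: np.ndarray


def _sample_cluster(rng: np.random.Generator, n: int, shape: str) -> np.ndarray:
    if shape == "gaussian":
        return rng.normal(size=(n, 2))
    if shape == "collinear":
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        t = rng.uniform(-1.0, 1.0, size=n)
        return t[:, None] * direction
    # convex-polygon: uniform rejection sampling inside the hull of 8
    # uniform points in [-1, 1]^2
    verts = rng.uniform(-1.0, 1.0, size=(8, 2))
    poly_ps = PointSet(verts)
    hull = convex_hull(poly_ps)
    out = np.empty((n, 2))
    got = 0
    for _ in range(1000):
        batch = rng.uniform(-1.0, 1.0, size=(max(4 * n, 32), 2))
        for q in batch:
            if contains_point(poly_ps, hull, q):
                out[got] = q
                got += 1
                if got == n:
                    return out
    raise ValueError("infeasible spec: rejection sampling failed")  # pragma: no cover


def _place_centers(
    rng: np.random.Generator, k: int, separation: float, r_max: float
) -> np.ndarray:
    """Centers scaled so the minimum pairwise distance equals
    separation * r_max exactly."""
    if k == 1:
        return np.zeros((1, 2))
    for _ in range(100):
        C = rng.uniform(0.0, 1.0, size=(k, 2))
        diff = C[:, None, :] - C[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        d0 = d[np.triu_indices(k, 1)].min()
        if d0 > 1e-3:
            return C * (separation * max(r_max, 1e-12) / d0)
    raise ValueError("infeasible spec: could not place distinct cluster centers")


def _build_level(spec: SyntheticSpec, rng: np.random.Generator, depth_left: int):
    """Returns (coords relative to this node, leaf labels 0-based, record, radius)."""
    if depth_left == 0:
        pts = _sample_cluster(rng, spec.points_per_cluster, spec.shape)
        radius = float(np.linalg.norm(pts, axis=1).max()) if len(pts) else 0.0
        return pts, np.zeros(len(pts), dtype=int), {"type": "cluster"}, radius

    children = [
        _build_level(spec, rng, depth_left - 1) for _ in range(spec.n_clusters)
    ]
    r_child = max(c[3] for c in children)
    centers = _place_centers(rng, spec.n_clusters, spec.separation, r_child)
    coords_parts = []
    labels_parts = []
    records = []
    offset = 0
    for (pts, labs, rec, _), c in zip(children, centers):
        coords_parts.append(pts + c)
        labels_parts.append(labs + offset)
        records.append({"center": c.tolist(), **rec})
        offset += int(labs.max()) + 1
    coords = np.vstack(coords_parts)
    radius = float(np.linalg.norm(coords, axis=1).max())
    return (
        coords,
        np.concatenate(labels_parts),
        {"type": "group", "children": records},
        radius,
    )


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Seed-deterministic synthetic point set satisfying the spec's planted
    structure; measured separation is >= the requested ratio by construction."""

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    coords, labels0, record, _ = _build_level(spec, rng, spec.hierarchy_depth)
    labels = labels0 + 1
    n_leaf = int(labels.max())
    centers = np.vstack(
        [coords[labels == lab].mean(axis=0) for lab in range(1, n_leaf + 1)]
    )

    n_out = int(round(spec.outlier_fraction * len(coords)))
    if n_out > 0:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        mid = (lo + hi) / 2
        half = (hi - lo) / 2 * 1.5
        out_pts = rng.uniform(mid - half, mid + half, size=(n_out, 2))
        d = np.linalg.norm(out_pts[:, None, :] - centers[None, :, :], axis=2)
        out_labels = d.argmin(axis=1) + 1
        outlier_idx = np.arange(len(coords), len(coords) + n_out)
        coords = np.vstack([coords, out_pts])
        labels = np.concatenate([labels, out_labels])
    else:
        outlier_idx = np.empty(0, dtype=int)

    return SyntheticData(
        points=PointSet(coords, labels),
        centers=centers,
        hierarchy=record,
        outlier_indices=outlier_idx,
    )
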