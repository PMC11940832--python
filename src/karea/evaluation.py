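"""Clustering evaluation: normalised mutual information and total hull area.

NMI(C, C') = I(C, C') / sqrt(En(C) * En(C')), computed from the contingency
table with natural logarithms (the ratio is base-invariant).  When either
labeling has zero entropy the formula is 0/0; the convention here is 1 when
the two labelings induce identical partitions and 0 otherwise.
"""

from __future__ import annotations

import numpy as np

from .geometry import PointSet, convex_hull


def contingency_table(true_labels, pred_labels) -> np.ndarray:
    """Counts n_uv of points with true label u and predicted label v."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.ndim != 1 or t.shape != p.shape:
        raise ValueError("label vectors must be 1D and of equal length")
    if t.size < 1:
        raise ValueError("label vectors must be non-empty")
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    counts = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return counts


def _entropy(marginal: np.ndarray, n: int) -> float:
    p = marginal[marginal > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(true_labels, pred_labels) -> float:
    """Normalised mutual information in [0, 1] between two labelings."""
    counts = contingency_table(true_labels, pred_labels)
    n = int(counts.sum())
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    ht = _entropy(row, n)
    hp = _entropy(col, n)
    if ht <= 0.0 or hp <= 0.0:
        # zero-entropy convention: identical partitions -> 1, else 0
        identical = bool(
            np.all((counts > 0).sum(axis=1) == 1)
            and np.all((counts > 0).sum(axis=0) == 1)
        )
        return 1.0 if identical else 0.0
    nzi, nzj = np.nonzero(counts)
    nij = counts[nzi, nzj].astype(float)
    mi = float((nij / n * np.log(nij * n / (row[nzi] * col[nzj]))).sum())
    return float(min(max(mi / np.sqrt(ht * hp), 0.0), 1.0))


def total_convex_area(ps: PointSet, labels) -> float:
    """Sum of per-cluster convex-hull areas; degenerate clusters contribute 0."""
    labels = np.asarray(labels)
    if labels.shape != (ps.n,):
        raise ValueError("labels must cover every point exactly once")
    total = 0.0
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        total += convex_hull(ps, members).area
    return float(total)
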