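"""Greedy divisive K-area clustering.

The algorithm maintains a set S of convex polygons (clusters), initialised
to the hull of all points.  Each round it considers, for every current
cluster C, every line through a pair of hull vertices of C, splits C by that
line, and scores the split by the area reduction

    delta = A(C) - [A(C1) + A(C2)].

The (cluster, line) pair with the largest delta is accepted, replacing C by
its two children, until the cluster-count cap K or the hierarchy-depth cap H
is reached, or no cluster admits a valid split.  The divisive history forms
a binary cluster tree whose leaves are the current clustering.

The total leaf area is non-increasing round over round; the ratio of total
areas between neighbouring rounds drives the automatic choice of K: once
the ratio stabilises near 1, further splitting removes almost no area.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    GeometryError,
    HullPolygon,
    PointSet,
    convex_hull,
    split_by_line,
)

#: relative tolerance below which two area reductions count as tied
DELTA_TIE_EPS = 1e-12


@dataclass
class SplitCandidate:
    """A separating line through hull vertices ``a_idx``, ``b_idx`` of a
    cluster, with the resulting sides and area reduction ``delta``."""

    a_idx: int
    b_idx: int
    delta: float
    side1: np.ndarray
    side2: np.ndarray
    hull1: HullPolygon | None = None
    hull2: HullPolygon | None = None


@dataclass
class ClusterNode:
    """One cluster in the divisive tree (root depth is 1)."""

    node_id: int
    members: np.ndarray
    hull: HullPolygon
    depth: int
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    split: SplitCandidate | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class RoundRecord:
    """Per-round log entry: after this round the clustering has ``k`` leaves."""

    round: int
    k: int
    h: int
    total_area: float
    ratio: float
    split_node: int | None
    delta: float


@dataclass
class KACParams:
    """Caps for the greedy loop: cluster count ``k`` and/or tree depth ``h``.

    ``None`` means unlimited; at least one cap must be finite.
    """

    k: int | None = None
    h: int | None = None

    def validate(self) -> None:
        if self.k is None and self.h is None:
            raise ValueError("at least one of k, h must be finite")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.h is not None and self.h < 1:
            raise ValueError("h must be >= 1")


@dataclass
class ClusterTree:
    """Binary divisive tree; ``leaves`` (in list order) are the clustering S."""

    root: ClusterNode
    leaves: list[ClusterNode]
    rounds: list[RoundRecord]
    n_points: int
    notes: list[str] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        """Per-point cluster ids 1..k, numbered by current leaf order."""
        out = np.empty(self.n_points, dtype=int)
        for i, leaf in enumerate(self.leaves, start=1):
            out[leaf.members] = i
        return out

    def nodes(self) -> dict[int, ClusterNode]:
        out: dict[int, ClusterNode] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            out[node.node_id] = node
            if node.children is not None:
                stack.extend(node.children)
        return out

    def total_leaf_area(self) -> float:
        return float(sum(leaf.hull.area for leaf in self.leaves))

    def leaves_at_round(self, k: int) -> list[ClusterNode]:
        """Replay the split log to recover the leaf set when it had ``k`` leaves."""
        if not 1 <= k <= len(self.rounds):
            raise ValueError(f"no round with k={k} in this tree")
        nodes = self.nodes()
        leaves = [self.root]
        for rec in self.rounds[1:k]:
            parent = nodes[rec.split_node]
            pos = leaves.index(parent)
            leaves[pos : pos + 1] = list(parent.children)
        return leaves

    def labels_at_round(self, k: int) -> np.ndarray:
        out = np.empty(self.n_points, dtype=int)
        for i, leaf in enumerate(self.leaves_at_round(k), start=1):
            out[leaf.members] = i
        return out


@dataclass
class KSelectionProfile:
    """Total leaf areas per round and neighbouring-round ratios.

    ``total_areas[r-1]`` is the total hull area with r clusters;
    ``ratios[r-1] = total_areas[r-1] / total_areas[r-2]`` with the first
    ratio defined as 0.  When a previous total is exactly 0 the ratio is
    defined as 1 (no further area can be removed).
    """

    total_areas: np.ndarray
    ratios: np.ndarray

    @property
    def k_max(self) -> int:
        return len(self.total_areas)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(1, self.k_max + 1),
                "total_area": self.total_areas,
                "ratio": self.ratios,
            }
        )


def enumerate_candidates(node: ClusterNode, ps: PointSet) -> list[SplitCandidate]:
    """All valid separating lines through hull-vertex pairs of a leaf cluster.

    Every unordered pair of ring vertices defines a raw candidate
    (|P(C)|·(|P(C)|-1)/2 lines); candidates whose second side is empty
    (all points on the closed side) are discarded.  Order is deterministic:
    ring-position pairs (i, j), i < j.
    """

    V = node.hull.vertices
    A = node.hull.area
    out: list[SplitCandidate] = []
    parent_vertices = set(int(v) for v in V)
    for i in range(len(V)):
        for j in range(i + 1, len(V)):
            a_idx, b_idx = int(V[i]), int(V[j])
            s1, s2 = split_by_line(ps, node.members, a_idx, b_idx)
            if s1.size == 0 or s2.size == 0:
                continue
            h1 = convex_hull(ps, s1)
            h2 = convex_hull(ps, s2)
            child_vertices = set(int(v) for v in h1.vertices) | set(
                int(v) for v in h2.vertices
            )
            if not parent_vertices <= child_vertices:
                raise GeometryError(
                    "parent hull vertex missing from child hulls after split"
                )
            delta = A - (h1.area + h2.area)
            if delta < -1e-9 * (A + 1e-300):
                raise GeometryError("split increased total area beyond tolerance")
            out.append(
                SplitCandidate(
                    a_idx=a_idx,
                    b_idx=b_idx,
                    delta=max(delta, 0.0),
                    side1=s1,
                    side2=s2,
                    hull1=h1,
                    hull2=h2,
                )
            )
    return out


def _candidate_beats(c: SplitCandidate, b: SplitCandidate, eps: float) -> bool:
    """Tie-broken comparison: larger delta, then larger smaller side, then
    lexicographically smaller (a_idx, b_idx)."""
    if c.delta > b.delta + eps:
        return True
    if c.delta < b.delta - eps:
        return False
    cm = min(c.side1.size, c.side2.size)
    bm = min(b.side1.size, b.side2.size)
    if cm != bm:
        return cm > bm
    return (c.a_idx, c.b_idx) < (b.a_idx, b.b_idx)


def best_split(node: ClusterNode, ps: PointSet) -> SplitCandidate | None:
    """The candidate maximising delta for one leaf, or None if unsplittable."""
    eps = DELTA_TIE_EPS * node.hull.area
    best: SplitCandidate | None = None
    for cand in enumerate_candidates(node, ps):
        if best is None or _candidate_beats(cand, best, eps):
            best = cand
    return best


def kac_cluster(ps: PointSet, params: KACParams) -> ClusterTree:
    """Run the greedy divisive K-area algorithm.

    Deterministic: no randomness anywhere; ties are broken by creation order
    across clusters and by (smaller-side size, vertex indices) within one.
    Stops at the cluster cap, the depth cap, or when no leaf has a valid
    split (the run then ends with fewer leaves, recorded in ``tree.notes``).
    """

    params.validate()
    n = ps.n
    K = params.k
    H = params.h
    notes: list[str] = []
    if K is not None and K > n:
        msg = f"K={K} exceeds N={n}; capped at N"
        warnings.warn(msg)
        notes.append(msg)
        K = n

    root = ClusterNode(0, np.arange(n), convex_hull(ps), depth=1)
    next_id = 1
    leaves: list[ClusterNode] = [root]
    k, h = 1, 1
    rounds = [RoundRecord(1, 1, 1, root.hull.area, 0.0, None, 0.0)]
    cache: dict[int, SplitCandidate | None] = {}
    eps = DELTA_TIE_EPS * root.hull.area

    while (K is None or k < K) and (H is None or h < H):
        chosen_leaf: ClusterNode | None = None
        chosen: SplitCandidate | None = None
        # creation order = node_id order; first strict improvement wins ties
        for leaf in sorted(leaves, key=lambda nd: nd.node_id):
            if leaf.node_id not in cache:
                cache[leaf.node_id] = best_split(leaf, ps)
            cand = cache[leaf.node_id]
            if cand is None:
                continue
            if chosen is None or cand.delta > chosen.delta + eps:
                chosen_leaf, chosen = leaf, cand
        if chosen is None:
            msg = f"no splittable cluster left at k={k}; stopping early"
            warnings.warn(msg)
            notes.append(msg)
            break

        c1 = ClusterNode(next_id, chosen.side1, chosen.hull1, chosen_leaf.depth + 1)
        c2 = ClusterNode(next_id + 1, chosen.side2, chosen.hull2, chosen_leaf.depth + 1)
        next_id += 2
        chosen_leaf.children = (c1, c2)
        chosen_leaf.split = chosen
        pos = leaves.index(chosen_leaf)
        leaves[pos : pos + 1] = [c1, c2]
        k += 1
        h = max(h, chosen_leaf.depth + 1)
        total = float(sum(leaf.hull.area for leaf in leaves))
        prev = rounds[-1].total_area
        ratio = total / prev if prev > 0 else 1.0
        ratio = min(max(ratio, 0.0), 1.0)
        rounds.append(
            RoundRecord(len(rounds) + 1, k, h, total, ratio, chosen_leaf.node_id, chosen.delta)
        )

    return ClusterTree(root=root, leaves=leaves, rounds=rounds, n_points=n, notes=notes)


def area_profile(ps: PointSet, k_max: int) -> tuple[KSelectionProfile, ClusterTree]:
    """Single incremental run to ``k_max`` leaves with a per-round area log.

    Returns the selection profile and the underlying tree (whose
    ``labels_at_round`` recovers the clustering at any intermediate k).
    """

    if not 1 <= k_max <= ps.n:
        raise ValueError("k_max must be in [1, N]")
    tree = kac_cluster(ps, KACParams(k=k_max))
    totals = np.array([rec.total_area for rec in tree.rounds])
    ratios = np.array([rec.ratio for rec in tree.rounds])
    return KSelectionProfile(total_areas=totals, ratios=ratios), tree


def select_k(profile: KSelectionProfile, tau: float = 0.8) -> int:
    """Smallest k whose later-round area ratios have all stabilised at >= tau.

    Returns ``k_max`` when no such k exists.  Ratios near 1 mean further
    splitting removes almost no hull area.
    """

    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    kmax = profile.k_max
    for k in range(1, kmax + 1):
        if all(profile.ratios[r - 1] >= tau for r in range(k + 1, kmax + 1)):
            return k
    return kmax


# ---------------------------------------------------------------------------
# export / import


def tree_to_dict(tree: ClusterTree) -> dict:
    nodes = {}
    for nid, node in sorted(tree.nodes().items()):
        split = None
        if node.split is not None:
            split = {
                "a_idx": node.split.a_idx,
                "b_idx": node.split.b_idx,
                "delta": node.split.delta,
            }
        nodes[str(nid)] = {
            "members": [int(m) for m in node.members],
            "vertices": [int(v) for v in node.hull.vertices],
            "interior": [int(v) for v in node.hull.interior],
            "area": node.hull.area,
            "depth": node.depth,
            "children": (
                [c.node_id for c in node.children] if node.children else None
            ),
            "split": split,
        }
    return {
        "n_points": tree.n_points,
        "root": tree.root.node_id,
        "leaves": [leaf.node_id for leaf in tree.leaves],
        "nodes": nodes,
        "rounds": [
            {
                "round": r.round,
                "k": r.k,
                "h": r.h,
                "total_area": r.total_area,
                "ratio": r.ratio,
                "split_node": r.split_node,
                "delta": r.delta,
            }
            for r in tree.rounds
        ],
        "notes": list(tree.notes),
    }


def tree_from_dict(d: dict) -> ClusterTree:
    nodes: dict[int, ClusterNode] = {}
    for nid_s, nd in d["nodes"].items():
        nid = int(nid_s)
        hull = HullPolygon(
            vertices=np.asarray(nd["vertices"], dtype=int),
            interior=np.asarray(nd["interior"], dtype=int),
            area=float(nd["area"]),
        )
        nodes[nid] = ClusterNode(
            node_id=nid,
            members=np.asarray(nd["members"], dtype=int),
            hull=hull,
            depth=int(nd["depth"]),
        )
    for nid_s, nd in d["nodes"].items():
        nid = int(nid_s)
        if nd["children"]:
            c1, c2 = (nodes[int(c)] for c in nd["children"])
            nodes[nid].children = (c1, c2)
        if nd["split"]:
            s = nd["split"]
            c1, c2 = nodes[nid].children
            nodes[nid].split = SplitCandidate(
                a_idx=int(s["a_idx"]),
                b_idx=int(s["b_idx"]),
                delta=float(s["delta"]),
                side1=c1.members,
                side2=c2.members,
                hull1=c1.hull,
                hull2=c2.hull,
            )
    rounds = [
        RoundRecord(
            round=int(r["round"]),
            k=int(r["k"]),
            h=int(r["h"]),
            total_area=float(r["total_area"]),
            ratio=float(r["ratio"]),
            split_node=(None if r["split_node"] is None else int(r["split_node"])),
            delta=float(r["delta"]),
        )
        for r in d["rounds"]
    ]
    return ClusterTree(
        root=nodes[int(d["root"])],
        leaves=[nodes[int(l)] for l in d["leaves"]],
        rounds=rounds,
        n_points=int(d["n_points"]),
        notes=list(d.get("notes", [])),
    )


def tree_to_json(tree: ClusterTree) -> str:
    return json.dumps(tree_to_dict(tree), indent=2, sort_keys=True)


def tree_from_json(s: str) -> ClusterTree:
    return tree_from_dict(json.loads(s))


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick serialisation: leaves C1..Ck (current leaf order), each child
    edge carrying the parent split's delta as branch length."""

    names = {leaf.node_id: f"C{i}" for i, leaf in enumerate(tree.leaves, start=1)}

    def fmt(x: float) -> str:
        return format(x, ".10g")

    def rec(node: ClusterNode) -> str:
        if node.children is None:
            return names[node.node_id]
        c1, c2 = node.children
        bl = fmt(node.split.delta)
        return f"({rec(c1)}:{bl},{rec(c2)}:{bl})"

    return rec(tree.root) + ";"


def rounds_to_dataframe(tree: ClusterTree) -> pd.DataFrame:
    """Round log as a table: round, k, h, total_area, ratio, cluster_split, delta."""
    return pd.DataFrame(
        {
            "round": [r.round for r in tree.rounds],
            "k": [r.k for r in tree.rounds],
            "h": [r.h for r in tree.rounds],
            "total_area": [r.total_area for r in tree.rounds],
            "ratio": [r.ratio for r in tree.rounds],
            "cluster_split": [r.split_node for r in tree.rounds],
            "delta": [r.delta for r in tree.rounds],
        }
    )
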