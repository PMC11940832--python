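import json
import time

import dendropy
import numpy as np
import pytest

from karea.core import (
    KACParams,
    KSelectionProfile,
    area_profile,
    best_split,
    enumerate_candidates,
    kac_cluster,
    rounds_to_dataframe,
    select_k,
    tree_from_json,
    tree_to_dict,
    tree_to_json,
    tree_to_newick,
)
from karea.evaluation import nmi
from karea.geometry import PointSet, convex_hull
from conftest import blob_points
from oracles import brute_best_delta, brute_candidates


def leaf_node(ps, members=None):
    tree = kac_cluster(ps, KACParams(k=1))
    if members is None:
        return tree.root
    # build a standalone leaf over a member subset
    from karea.core import ClusterNode

    members = np.asarray(members, dtype=int)
    return ClusterNode(0, members, convex_hull(ps, members), depth=1)


class TestEnumerateCandidates:
    def test_pentagon_has_ten_raw_lines(self):
        ang = np.linspace(0, 2 * np.pi, 6)[:-1]
        ps = PointSet(np.c_[np.cos(ang), np.sin(ang)])
        node = leaf_node(ps)
        assert len(node.hull.vertices) == 5  # 5*4/2 = 10 raw candidate lines
        cands = enumerate_candidates(node, ps)
        assert len(cands) <= 10
        assert all(c.side1.size and c.side2.size for c in cands)

    def test_two_point_cluster_is_unsplittable(self):
        ps = PointSet(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert enumerate_candidates(leaf_node(ps), ps) == []
        assert best_split(leaf_node(ps), ps) is None

    def test_hexagon_deltas_match_brute_force(self):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        ps = PointSet(np.c_[np.cos(ang), np.sin(ang)] + 2.0)
        node = leaf_node(ps)
        cands = enumerate_candidates(node, ps)
        _, brute = brute_candidates(ps.coords, np.arange(ps.n))
        assert len(cands) == len(brute)
        for c in cands:
            a = tuple(ps.coords[c.a_idx])
            b = tuple(ps.coords[c.b_idx])
            key = (a, b) if a <= b else (b, a)
            assert c.delta == pytest.approx(brute[key], abs=1e-12)

    def test_candidate_deltas_are_nonnegative(self):
        ps = blob_points(3)
        node = leaf_node(ps)
        assert all(c.delta >= 0 for c in enumerate_candidates(node, ps))


class TestBestSplit:
    def test_two_squares_best_split_attains_exhaustive_maximum(self, two_squares):
        node = leaf_node(two_squares)
        cand = best_split(node, two_squares)
        assert cand.delta == pytest.approx(
            brute_best_delta(two_squares.coords, np.arange(8)), rel=1e-12
        )
        # the corner rows of the two squares are collinear, so the cut along
        # y=0 leaves two zero-area children and removes the whole joint area
        assert cand.delta == pytest.approx(node.hull.area)

    def test_triangle_split_removes_full_area_with_tie_break(self):
        ps = PointSet(np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]]))
        node = leaf_node(ps)
        cand = best_split(node, ps)
        assert cand.delta == pytest.approx(node.hull.area)
        # all valid candidates tie at delta = area; the documented tie-break
        # (larger smaller side, then smallest (a, b)) must pick the first
        cands = enumerate_candidates(node, ps)
        expected = min(
            cands,
            key=lambda c: (-min(c.side1.size, c.side2.size), c.a_idx, c.b_idx),
        )
        assert (cand.a_idx, cand.b_idx) == (expected.a_idx, expected.b_idx)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ps = PointSet(rng.normal(size=(30, 2)))
        cand = best_split(leaf_node(ps), ps)
        assert cand.delta == pytest.approx(
            brute_best_delta(ps.coords, np.arange(30)), rel=1e-9, abs=1e-12
        )


class TestKacCluster:
    def test_k1_returns_single_hull(self):
        ps = blob_points(0)
        tree = kac_cluster(ps, KACParams(k=1))
        assert len(tree.leaves) == 1
        assert np.array_equal(tree.labels(), np.ones(ps.n, dtype=int))

    def test_three_far_triangles_recovered_exactly(self, three_triangles):
        tree = kac_cluster(three_triangles, KACParams(k=3))
        assert nmi(three_triangles.labels, tree.labels()) == pytest.approx(1.0)
        assert tree.total_leaf_area() == pytest.approx(1.5)

    def test_leaves_partition_and_area_monotone_every_round(self):
        ps = blob_points(7)
        tree = kac_cluster(ps, KACParams(k=6))
        totals = [r.total_area for r in tree.rounds]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(totals, totals[1:]))
        assert all(r.delta >= 0 for r in tree.rounds)
        for k in range(1, len(tree.rounds) + 1):
            labels = tree.labels_at_round(k)
            assert len(np.unique(labels)) == k
            assert labels.shape == (ps.n,)

    def test_greedy_round_deltas_match_exhaustive_max(self):
        rng = np.random.default_rng(12)
        ps = PointSet(rng.normal(size=(35, 2)))
        tree = kac_cluster(ps, KACParams(k=4))
        for rec in tree.rounds[1:]:
            leaves_before = tree.leaves_at_round(rec.k - 1)
            deltas = [
                brute_best_delta(ps.coords, leaf.members) for leaf in leaves_before
            ]
            best = max(d for d in deltas if d is not None)
            assert rec.delta == pytest.approx(max(best, 0.0), rel=1e-9, abs=1e-12)

    def test_deterministic_repeat_runs(self):
        ps = blob_points(4)
        t1 = kac_cluster(ps, KACParams(k=5))
        t2 = kac_cluster(ps, KACParams(k=5))
        assert np.array_equal(t1.labels(), t2.labels())
        assert tree_to_json(t1) == tree_to_json(t2)

    def test_rigid_motion_leaves_partition_unchanged(self):
        ps = blob_points(9)
        rng = np.random.default_rng(99)
        theta = rng.uniform(0.1, 1.0)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = PointSet(ps.coords @ R.T + [13.7, -4.2])
        l1 = kac_cluster(ps, KACParams(k=4)).labels()
        l2 = kac_cluster(moved, KACParams(k=4)).labels()
        assert nmi(l1, l2) == pytest.approx(1.0)

    def test_depth_cap_stops_growth(self):
        ps = blob_points(2)
        tree = kac_cluster(ps, KACParams(h=2))
        assert max(leaf.depth for leaf in tree.leaves) == 2
        assert len(tree.leaves) == 2  # one split takes depth from 1 to 2

    def test_k_exceeding_n_capped_with_warning(self):
        ps = PointSet(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        with pytest.warns(UserWarning):
            tree = kac_cluster(ps, KACParams(k=10))
        assert len(tree.leaves) <= 3
        assert tree.notes

    def test_invalid_params_rejected(self):
        ps = blob_points(0)
        with pytest.raises(ValueError):
            kac_cluster(ps, KACParams(k=0))
        with pytest.raises(ValueError):
            kac_cluster(ps, KACParams())

    def test_collinear_input_terminates_early(self):
        ps = PointSet(np.c_[np.arange(6.0), np.arange(6.0)])
        with pytest.warns(UserWarning):
            tree = kac_cluster(ps, KACParams(k=3))
        assert len(tree.leaves) == 1
        assert tree.total_leaf_area() == 0.0


class TestAreaProfileAndSelectK:
    def test_profile_starts_at_zero_ratio_and_stays_in_unit_interval(self):
        ps = blob_points(1)
        profile, _ = area_profile(ps, 8)
        assert profile.ratios[0] == 0.0
        assert np.all(profile.ratios >= 0.0) and np.all(profile.ratios <= 1.0)
        assert np.all(np.diff(profile.total_areas) <= 1e-9)

    def test_select_k_forced_example(self):
        profile = KSelectionProfile(
            total_areas=np.array([100.0, 10.0, 1.0, 0.95, 0.92]),
            ratios=np.array([0.0, 0.1, 0.1, 0.95, 0.97]),
        )
        assert select_k(profile, tau=0.8) == 3

    def test_select_k_degenerate_single_cluster(self):
        profile = KSelectionProfile(
            total_areas=np.array([10.0, 9.0, 8.5]),
            ratios=np.array([0.0, 0.9, 0.94]),
        )
        assert select_k(profile, tau=0.8) == 1

    def test_select_k_returns_k_max_without_stabilisation(self):
        profile = KSelectionProfile(
            total_areas=np.array([10.0, 5.0, 2.0]),
            ratios=np.array([0.0, 0.5, 0.4]),
        )
        assert select_k(profile, tau=0.8) == 3

    def test_profile_k_max_bounds(self):
        ps = blob_points(0)
        with pytest.raises(ValueError):
            area_profile(ps, 0)
        with pytest.raises(ValueError):
            area_profile(ps, ps.n + 1)


class TestExport:
    def test_single_leaf_newick(self):
        ps = PointSet(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        tree = kac_cluster(ps, KACParams(k=1))
        assert tree_to_newick(tree) == "C1;"

    def test_three_leaf_newick_parses_as_binary_tree(self, three_triangles):
        tree = kac_cluster(three_triangles, KACParams(k=3))
        nwk = tree_to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(parsed.leaf_nodes()) == 3
        internal = [n for n in parsed if not n.is_leaf()]
        assert len(internal) == 2

    def test_json_round_trip_is_identity(self):
        ps = blob_points(6)
        tree = kac_cluster(ps, KACParams(k=5))
        s = tree_to_json(tree)
        tree2 = tree_from_json(s)
        assert tree_to_json(tree2) == s
        assert np.array_equal(tree2.labels(), tree.labels())
        assert tree_to_dict(tree2) == json.loads(s)

    def test_round_log_dataframe_layout(self):
        ps = blob_points(8)
        tree = kac_cluster(ps, KACParams(k=4))
        df = rounds_to_dataframe(tree)
        assert list(df.columns) == [
            "round", "k", "h", "total_area", "ratio", "cluster_split", "delta",
        ]
        assert df["round"].tolist() == [1, 2, 3, 4]


def test_runtime_scaling_is_coarsely_polynomial():
    """Doubling N must not blow past the expected cubic-log growth envelope."""

    def median_time(n: int) -> float:
        ts = []
        for rep in range(3):
            ps = blob_points(rep, points_per_cluster=n // 4)
            t0 = time.process_time()
            kac_cluster(ps, KACParams(k=4))
            ts.append(time.process_time() - t0)
        return float(np.median(ts))

    t_small = median_time(60)
    t_big = median_time(120)
    # N^3 log N predicts ~9x; allow a wide envelope for constant factors
    assert t_big <= 64 * t_small + 0.5
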