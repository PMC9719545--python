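import numpy as np
import pytest

import dualcomm as dc
from dualcomm.communities import Bisection, fiedler, bisect, cut_set, cut_path
from dualcomm.graph import laplacian
from dualcomm.dual import build_dual, dual_laplacian

from conftest import random_weighted_lattice


class TestFiedler:
    def test_unit_path(self):
        g = dc.PlaneGraph.from_edgelist(
            [("a", "b"), ("b", "c")],
            {"a": (0, 0), "b": (1, 0), "c": (2, 0)})
        lam2, v2 = fiedler(laplacian(g))
        assert abs(lam2 - 1.0) < 1e-12

    def test_complete_graph_k4(self):
        import itertools
        g = dc.PlaneGraph.from_edgelist(
            list(itertools.combinations(range(4), 2)),
            {0: (0, 0), 1: (1, 0), 2: (0.5, 1), 3: (0.5, 0.4)})
        lam2, _ = fiedler(laplacian(g))
        assert abs(lam2 - 4.0) < 1e-10

    def test_weak_bridge_bounded_by_cut(self, barbell):
        lam2, _ = fiedler(laplacian(barbell))
        assert lam2 <= (2.0 / 3.0) * 1e-6 * (1 + 1e-9)

    def test_sign_convention_deterministic(self, weighted_6x6):
        l1, v1 = fiedler(laplacian(weighted_6x6))
        l2, v2 = fiedler(laplacian(weighted_6x6))
        assert l1 == l2 and np.array_equal(v1, v2)
        nz = np.flatnonzero(np.abs(v1) > 1e-12)
        assert v1[nz[0]] > 0

    def test_disconnected_signalled(self):
        L = np.array([[1., -1, 0, 0], [-1, 1, 0, 0],
                      [0, 0, 1, -1], [0, 0, -1, 1]])
        with pytest.raises(dc.DisconnectedError):
            fiedler(L)

    def test_sparse_branch_matches_dense(self):
        g = dc.square_lattice(24, 24).graph  # 576 nodes: iterative solver
        lam_sparse, v_sparse = fiedler(laplacian(g))
        import scipy.linalg
        vals = scipy.linalg.eigh(laplacian(g), eigvals_only=True,
                                 subset_by_index=(1, 1))
        assert abs(lam_sparse - vals[0]) < 1e-8


class TestBisect:
    def test_barbell_splits_into_triangles(self, barbell):
        bis = bisect(barbell)
        assert {frozenset(bis.community1), frozenset(bis.community2)} == \
            {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        assert bis.boundary_disconnects

    def test_weakened_lattice_splits_left_right(self):
        lat = dc.square_lattice(8, 5, "cut_set", 1e-3)
        bis = bisect(lat.graph)
        assert {bis.community1, bis.community2} == \
            {lat.left_nodes, lat.right_nodes}
        assert set(bis.boundary_edges) == set(lat.boundary_edges)

    def test_strong_vein_splits_dual_left_right(self):
        lat = dc.square_lattice(9, 6, "cut_path", 1e3)
        dual = build_dual(lat.graph)
        bis = bisect(dual)
        got = {frozenset(bis.community1), frozenset(bis.community2)}
        left = frozenset(c for c in range(dual.n_nodes)
                         if dual.coords[c, 0] < lat.split_x)
        right = frozenset(range(dual.n_nodes)) - left
        assert got == {left, right}
        assert set(bis.boundary_edges) == set(lat.boundary_edges)


class TestCutSet:
    def test_single_edge_bound_tight(self):
        g = dc.PlaneGraph.from_edgelist([(0, 1)], {0: (0, 0), 1: (1, 0)},
                                        [3.0])
        bis = bisect(g)
        assert bis.boundary_edges == (0,)
        assert abs(bis.mu2 - 6.0) < 1e-12
        assert abs(bis.lam2 - bis.mu2) < 1e-10

    def test_barbell_formula(self, barbell):
        bis = bisect(barbell)
        assert abs(bis.mu2 - (6 / 9) * 1e-6) < 1e-18

    def test_bound_holds_for_arbitrary_splits(self):
        g = random_weighted_lattice(5, 5, 11)
        lam2, _ = fiedler(laplacian(g))
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = rng.random(g.n_nodes) < rng.uniform(0.2, 0.8)
            if mask.all() or not mask.any():
                continue
            c1 = frozenset(n for n, m in zip(g.nodes, mask) if m)
            c2 = frozenset(g.nodes) - c1
            bis = Bisection("primal", c1, c2, lam2, np.zeros(g.n_nodes), 0.0)
            _, mu2 = cut_set(bis, g)
            assert lam2 <= mu2 * (1 + 1e-12)


class TestCutPath:
    def test_two_faces_bound_tight(self, two_squares):
        dual = build_dual(two_squares)
        bis = bisect(dual)
        shared = two_squares.edge_index((1, 0), (1, 1))
        assert bis.boundary_edges == (shared,)
        assert abs(bis.mu2 - 2.0 / 4.0) < 1e-12
        assert abs(bis.lam2 - bis.mu2) < 1e-12

    def test_homogeneous_lattice_bound(self):
        g = dc.square_lattice(7, 5).graph
        bis = bisect(build_dual(g))
        assert bis.lam2 <= bis.mu2 * (1 + 1e-12)

    def test_strong_vein_bound_within_one_percent(self):
        lat = dc.square_lattice(21, 10, "cut_path", 1e4)
        bis = bisect(build_dual(lat.graph))
        assert abs(bis.mu2 - bis.lam2) / bis.mu2 < 0.01
        assert bis.boundary_is_path
        assert bis.boundary_disconnects


class TestHierarchy:
    def test_depth_one_gives_two_leaves(self, weighted_6x6):
        tree = dc.hierarchical_decompose(weighted_6x6, 1, side="primal")
        assert len(tree.leaves()) == 2

    def test_single_vein_dual_split(self):
        vh = dc.vein_hierarchy_lattice(levels=1)
        tree = dc.hierarchical_decompose(vh.graph, 1, side="dual")
        assert sorted(map(sorted, tree.leaf_node_sets())) == \
            sorted(map(sorted, vh.truth))

    def test_nested_veins_recovered(self):
        vh = dc.vein_hierarchy_lattice(levels=2)
        tree = dc.hierarchical_decompose(vh.graph, 2, side="dual")
        assert sorted(map(sorted, tree.leaf_node_sets())) == \
            sorted(map(sorted, vh.truth))

    def test_leaves_cover_root(self, weighted_6x6):
        tree = dc.hierarchical_decompose(weighted_6x6, 2, side="dual")
        covered = set().union(*tree.leaf_node_sets())
        assert covered == set(weighted_6x6.nodes)
        for leaf in tree.leaves():
            assert leaf.node_set <= tree.node_set

    def test_small_branch_stops_gracefully(self):
        g = dc.square_lattice(3, 2).graph
        tree = dc.hierarchical_decompose(g, 3, side="dual")
        assert tree.leaves()  # no exception; stop reasons recorded

    def test_deterministic(self):
        vh = dc.vein_hierarchy_lattice(levels=2)
        t1 = dc.hierarchical_decompose(vh.graph, 2, side="dual")
        t2 = dc.hierarchical_decompose(vh.graph, 2, side="dual")
        assert t1.leaf_node_sets() == t2.leaf_node_sets()
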