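import numpy as np
import pytest

import dualcomm as dc
from dualcomm.dual import (enumerate_faces, cycle_incidence, build_dual,
                           dual_laplacian, dual_from_cycle_basis)
from dualcomm.graph import build_incidence, solve_flow

from conftest import random_weighted_lattice


class TestFaceEnumeration:
    def test_square_has_one_interior_face(self, unit_square):
        fs = enumerate_faces(unit_square)
        assert fs.n_faces == 1
        assert fs.faces[0].area > 0       # counter-clockwise
        assert fs.outer.area < 0

    def test_two_squares_share_edge(self, two_squares):
        fs = enumerate_faces(two_squares)
        assert fs.n_faces == 2
        shared = two_squares.edge_index((1, 0), (1, 1))
        assert all(shared in f.edge_ids for f in fs.faces)

    @pytest.mark.parametrize("nx,ny", [(5, 5), (3, 7), (2, 2)])
    def test_lattice_face_count(self, nx, ny):
        g = dc.square_lattice(nx, ny).graph
        fs = enumerate_faces(g)
        assert fs.n_faces == g.n_edges - g.n_nodes + 1

    def test_euler_formula_with_outer_face(self, two_squares):
        fs = enumerate_faces(two_squares)
        N, M = two_squares.n_nodes, two_squares.n_edges
        assert N - M + (fs.n_faces + 1) == 2


class TestCycleIncidence:
    def test_columns_are_cycles(self, two_squares):
        C = cycle_incidence(enumerate_faces(two_squares))
        I = build_incidence(two_squares)
        assert np.abs(I.T @ C).max() == 0

    def test_shared_edge_opposite_signs(self, two_squares):
        C = cycle_incidence(enumerate_faces(two_squares))
        shared = two_squares.edge_index((1, 0), (1, 1))
        assert C[shared, 0] * C[shared, 1] == -1

    def test_rank_on_random_lattice(self):
        g = random_weighted_lattice(6, 6, 2)
        C = cycle_incidence(enumerate_faces(g))
        assert np.linalg.matrix_rank(C) == g.n_edges - g.n_nodes + 1
        assert np.abs(build_incidence(g).T @ C).max() == 0

    def test_kvl_holds_for_solved_flows(self):
        g = random_weighted_lattice(5, 4, 7)
        rng = np.random.default_rng(1)
        P = rng.normal(size=g.n_nodes)
        P -= P.mean()
        F = solve_flow(g, P).flows
        C = cycle_incidence(enumerate_faces(g))
        assert np.abs(C.T @ (F / g.weights)).max() < 1e-9


class TestBuildDual:
    def test_two_squares(self, two_squares):
        d = build_dual(two_squares)
        assert d.n_nodes == 2 and d.edges == ((0, 1),)
        assert np.allclose(d.weights, [0.25])   # inverse of the shared weight

    def test_four_unit_squares(self):
        g = dc.square_lattice(3, 3).graph
        d = build_dual(g)
        assert d.n_nodes == 4 and d.n_edges == 4
        assert np.allclose(d.weights, 1.0)

    def test_lumped_parallel_edges(self):
        # theta graph: two faces sharing the two-edge path A-E-C
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"),
                 ("A", "E"), ("C", "E")]
        coords = {"A": (0, 0), "B": (1, -1), "C": (2, 0), "D": (1, 1),
                  "E": (1, 0.2)}
        w = {("A", "E"): 2.0, ("C", "E"): 4.0}
        weights = [w.get(e, 1.0) for e in edges]
        g = dc.PlaneGraph.from_edgelist(edges, coords, weights)
        d = build_dual(g)
        assert d.n_nodes == 2 and d.n_edges == 1
        assert np.allclose(d.weights, [1 / 2 + 1 / 4])

    def test_inverse_weight_relation(self, two_squares):
        d = build_dual(two_squares)
        shared = two_squares.edge_index((1, 0), (1, 1))
        assert 1.0 / d.weights[0] == two_squares.weights[shared]

    def test_degenerate_dual_rejected(self, unit_square):
        with pytest.raises(dc.GraphError):
            build_dual(unit_square)


class TestDualLaplacian:
    def test_two_unit_squares(self):
        edges = [((0, 0), (1, 0)), ((1, 0), (1, 1)), ((1, 1), (0, 1)),
                 ((0, 0), (0, 1)), ((1, 0), (2, 0)), ((2, 0), (2, 1)),
                 ((2, 1), (1, 1))]
        coords = {(i, j): (i, j) for i in range(3) for j in range(2)}
        g = dc.PlaneGraph.from_edgelist(edges, coords)
        assert np.allclose(dual_laplacian(g), [[1, -1], [-1, 1]])

    def test_null_vector_and_psd(self):
        g = random_weighted_lattice(5, 5, 3)
        Ls = dual_laplacian(g)
        assert np.allclose(Ls @ np.ones(Ls.shape[0]), 0)
        assert np.linalg.eigvalsh(Ls).min() > -1e-10

    def test_matches_independent_construction(self):
        """Entrywise agreement with a brute-force dual Laplacian assembled
        from the face adjacency."""
        g = random_weighted_lattice(5, 5, 4)
        fs = enumerate_faces(g)
        nf = fs.n_faces
        ref = np.zeros((nf, nf))
        for c in range(nf):
            for d_ in range(c + 1, nf):
                shared = set(fs.faces[c].edge_ids) & set(fs.faces[d_].edge_ids)
                wstar = sum(1.0 / g.weights[e] for e in shared)
                ref[c, d_] = ref[d_, c] = -wstar
        np.fill_diagonal(ref, -ref.sum(axis=1))
        assert np.abs(dual_laplacian(g) - ref).max() < 1e-12


class TestCycleBasisDual:
    def test_face_basis_reproduces_plane_dual(self):
        g = random_weighted_lattice(4, 5, 5)
        basis = [list(f.nodes) for f in enumerate_faces(g).faces]
        d_faces = dual_from_cycle_basis(g, basis)
        d_plane = build_dual(g)
        assert d_faces.edges == d_plane.edges
        assert np.allclose(
            sorted(d_faces.weights), sorted(d_plane.weights))

    def test_k4(self):
        g = dc.PlaneGraph.from_edgelist(
            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
            {0: (0, 0), 1: (1, 0), 2: (0.5, 1), 3: (0.5, 0.4)})
        d = dual_from_cycle_basis(g)
        assert d.n_nodes == 3
        assert d.is_connected()

    def test_k5_nonplanar(self):
        import itertools
        coords = {i: (np.cos(2 * np.pi * i / 5), np.sin(2 * np.pi * i / 5))
                  for i in range(5)}
        g = dc.PlaneGraph.from_edgelist(
            list(itertools.combinations(range(5), 2)), coords)
        d = dual_from_cycle_basis(g)
        assert d.n_nodes == 10 - 5 + 1
        assert d.is_connected()

    def test_wrong_basis_size_rejected(self, two_squares):
        with pytest.raises(dc.GraphError):
            dual_from_cycle_basis(two_squares, [[(0, 0), (1, 0), (1, 1),
                                                 (0, 1)]])
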