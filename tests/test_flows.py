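import numpy as np
import pytest

import dualcomm as dc
from dualcomm.flows import (sensitivity_matrix, sensitivity_primal,
                            sensitivity_dual, line_outage_flow_change,
                            edge_distance_matrix, edge_communities_from_nodes,
                            flow_ratio, BridgeEdgeError)
from dualcomm.graph import solve_flow

from conftest import random_weighted_lattice


class TestSensitivityPrimal:
    def test_single_edge_self_sensitivity(self):
        g = dc.PlaneGraph.from_edgelist([(0, 1)], {0: (0, 0), 1: (1, 0)},
                                        [5.0])
        assert abs(sensitivity_primal(g, 0, 0) - 1.0) < 1e-12

    def test_square_cycle_opposite_sides(self, unit_square):
        e = unit_square.edge_index(0, 1)
        l = unit_square.edge_index(2, 3)
        eta = sensitivity_primal(unit_square, e, l)
        assert abs(abs(eta) - 0.25) < 1e-12  # 3/4 vs 1/4 split, diff edge
        assert abs(sensitivity_primal(unit_square, e, e) - 0.75) < 1e-12

    def test_self_sensitivity_in_unit_interval(self):
        g = random_weighted_lattice(5, 4, 2)
        H = sensitivity_matrix(g)
        self_eta = np.diag(H)
        assert np.all(self_eta >= -1e-12) and np.all(self_eta <= 1 + 1e-12)


class TestPrimalDualEquivalence:
    def test_random_weighted_lattices(self):
        for seed in range(3):
            g = random_weighted_lattice(6, 6, seed)
            H = sensitivity_matrix(g)
            dual = dc.build_dual(g)
            for e in range(0, g.n_edges, 7):
                col = sensitivity_dual(g, e, dual=dual)
                assert np.abs(col - H[:, e]).max() < 1e-9

    def test_bridge_edge_zero_elsewhere(self, barbell):
        e = barbell.edge_index(2, 3)     # the bridge
        col = sensitivity_dual(barbell, e)
        assert col[e] == 1.0
        mask = np.ones(barbell.n_edges, bool)
        mask[e] = False
        assert np.abs(col[mask]).max() == 0.0
        # primal form agrees up to the conditioning of the weak bridge
        col_p = sensitivity_primal(barbell, e)
        assert np.abs(col_p[mask]).max() < 1e-8


class TestLineOutage:
    def test_matches_delete_and_resolve(self):
        g = random_weighted_lattice(4, 4, 9)
        P = np.zeros(g.n_nodes)
        P[0], P[-1] = 1.5, -1.5
        st = solve_flow(g, P)
        for e in range(g.n_edges):
            dF = line_outage_flow_change(g, st, e)
            keep = [k for k in range(g.n_edges) if k != e]
            sub = g.edge_subgraph(keep, extra_nodes=g.nodes)
            st2 = solve_flow(sub, P)
            post = st.flows + dF
            for k in range(sub.n_edges):
                orig = g.edge_index(*sub.edge_nodes(k))
                assert abs(post[orig] - st2.flows[k]) < 1e-10
            assert post[e] == 0.0

    def test_double_path_reroutes_by_conductance(self):
        # two parallel 2-edge paths between source and sink
        edges = [(0, 1), (1, 3), (0, 2), (2, 3)]
        coords = {0: (0, 0), 1: (1, 1), 2: (1, -1), 3: (2, 0)}
        g = dc.PlaneGraph.from_edgelist(edges, coords, [1, 1, 2, 2])
        st = solve_flow(g, [3.0, 0, 0, -3.0])
        e = g.edge_index(0, 1)
        dF = line_outage_flow_change(g, st, e)
        post = st.flows + dF
        assert abs(post[g.edge_index(0, 2)] - 3.0) < 1e-10

    def test_bridge_failure_rejected(self, barbell):
        e = barbell.edge_index(2, 3)
        P = np.zeros(6)
        P[0], P[5] = 1.0, -1.0
        st = solve_flow(barbell, P)
        with pytest.raises(BridgeEdgeError):
            line_outage_flow_change(barbell, st, e)


class TestEdgeDistance:
    def test_small_path(self):
        g = dc.PlaneGraph.from_edgelist(
            [(0, 1), (1, 2), (2, 3)],
            {i: (i, 0) for i in range(4)})
        d = edge_distance_matrix(g)
        assert d[0, 0] == 0 and d[0, 1] == 0 and d[0, 2] == 1

    def test_symmetry(self):
        g = random_weighted_lattice(4, 3, 1)
        d = edge_distance_matrix(g)
        assert np.array_equal(d, d.T)


class TestFlowRatio:
    def test_disconnected_halves_give_zero(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        coords = {0: (0, 0), 1: (1, 0), 2: (0.5, 1), 3: (3, 0),
                  4: (4, 0), 5: (3.5, 1)}
        g = dc.PlaneGraph.from_edgelist(edges, coords, check=False)
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = flow_ratio(g, labels)
        assert res.mean_ratio == 0.0

    def test_homogeneous_lattice_ratio_near_one_at_distance(self):
        lat = dc.square_lattice(9, 6)
        labels = edge_communities_from_nodes(lat.graph, lat.left_nodes,
                                             lat.right_nodes)
        res = flow_ratio(lat.graph, labels)
        assert 0.2 < res.mean_ratio <= 1.5
        assert set(res.table.columns) == {"edge", "distance", "ratio"}

    def test_weak_boundary_suppresses_ratio(self):
        strong = dc.square_lattice(9, 6, "cut_set", 1.0)
        weak = dc.square_lattice(9, 6, "cut_set", 1e-3)
        lab_s = edge_communities_from_nodes(strong.graph, strong.left_nodes,
                                            strong.right_nodes)
        lab_w = edge_communities_from_nodes(weak.graph, weak.left_nodes,
                                            weak.right_nodes)
        r_strong = flow_ratio(strong.graph, lab_s).mean_ratio
        r_weak = flow_ratio(weak.graph, lab_w).mean_ratio
        assert r_weak < 0.1 * r_strong

    def test_boundary_edges_never_trigger(self):
        lat = dc.square_lattice(6, 4, "cut_set", 0.5)
        labels = edge_communities_from_nodes(lat.graph, lat.left_nodes,
                                             lat.right_nodes)
        res = flow_ratio(lat.graph, labels)
        assert not set(res.table["edge"]) & set(lat.boundary_edges)
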