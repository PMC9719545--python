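"""Failure-sensitivity analysis in linear flow networks.

The response of the network flows to a unit dipole injection at the end
nodes of a *trigger edge* ``e`` is the sensitivity factor (the power-systems
"power transfer distribution factor")::

    eta_{e,l} = w_l  l_l^T I L^+ I^T l_e                       (primal form)
    eta_{e,l} = -(1/w_e) l_l^T C (L*)^+ C^T l_e     (l != e)   (dual form)

Both forms coincide exactly; the dual form shows that the *dual* Laplacian
controls failure spreading the same way the primal one does.  The sensitivity
factor also yields the flow change after the complete outage of a non-bridge
edge carrying flow ``F_e``::

    dF_l = eta_{e,l} * F_e / (1 - eta_{e,e})

The community flow-ratio statistic ``R`` compares failure-induced flow
changes in the *other* community with those in the *same* community at equal
unweighted edge distance, averaged over trigger edges and distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import PlaneGraph, FlowState, GraphError, build_incidence, \
    laplacian_pinv
from .dual import DualGraph, build_dual, cycle_incidence

__all__ = [
    "BridgeEdgeError",
    "sensitivity_matrix",
    "sensitivity_primal",
    "sensitivity_dual",
    "line_outage_flow_change",
    "edge_distance_matrix",
    "edge_communities_from_nodes",
    "edge_communities_from_faces",
    "flow_ratio",
    "FlowRatioResult",
]


class BridgeEdgeError(GraphError):
    """The operation is undefined for a bridge edge."""


def sensitivity_matrix(graph: PlaneGraph) -> np.ndarray:
    """All sensitivity factors at once: ``H[l, e] = eta_{e, l}`` (M x M)."""
    I = build_incidence(graph)
    Lp = laplacian_pinv(graph)
    return (graph.weights[:, None] * I) @ Lp @ I.T


def sensitivity_primal(graph: PlaneGraph, e: int, l: int | None = None):
    """Primal-form sensitivity factor(s) for trigger edge ``e``.

    Returns the scalar ``eta_{e,l}`` if ``l`` is given, else the full
    per-edge vector.
    """
    I = build_incidence(graph)
    Lp = laplacian_pinv(graph)
    col = graph.weights * (I @ (Lp @ I[e]))
    return float(col[l]) if l is not None else col


def sensitivity_dual(graph: PlaneGraph, e: int, l: int | None = None,
                     dual: DualGraph | None = None):
    """Dual-form sensitivity factor(s) for trigger edge ``e`` (``l != e``).

    Computed from the dual Laplacian via the cycle-flow correction to the
    particular solution ``dF_part = dP l_e``.  For a bridge edge (an edge on
    no cycle) the correction vanishes: all ``l != e`` entries are zero.
    The ``l == e`` entry of the returned vector carries the full flow change
    (cycle correction plus the particular term 1), making the vector
    directly comparable to the primal form.
    """
    if dual is None:
        dual = build_dual(graph)
    C = cycle_incidence(dual.faces)
    Lstar = C.T @ (C / graph.weights[:, None])
    rhs = C[e]
    if np.abs(rhs).max() == 0:   # bridge: no cycle uses e
        col = np.zeros(graph.n_edges)
        col[e] = 1.0
        return float(col[l]) if l is not None else col
    # L* is nonsingular when the dual is connected and has no outer-face
    # node; fall back to pseudoinverse otherwise.
    try:
        f = np.linalg.solve(Lstar, rhs)
    except np.linalg.LinAlgError:
        f = np.linalg.pinv(Lstar) @ rhs
    col = -(C @ f) / graph.weights[e]
    col[e] += 1.0
    return float(col[l]) if l is not None else col


def line_outage_flow_change(graph: PlaneGraph, flow: FlowState, e: int,
                            eta_col: np.ndarray | None = None) -> np.ndarray:
    """Flow changes after the complete failure of edge ``e``.

    The outage is emulated by a dipole injection that cancels the flow on
    ``e``: ``dF_l = eta_{e,l} F_e / (1 - eta_{e,e})`` for ``l != e`` and
    ``dF_e = -F_e``, so that ``F + dF`` is the post-outage flow pattern.
    Identical to deleting the edge and re-solving.

    Raises
    ------
    BridgeEdgeError
        If removing ``e`` would disconnect the network.
    """
    if eta_col is None:
        eta_col = sensitivity_primal(graph, e)
    denom = 1.0 - eta_col[e]
    if abs(denom) < 1e-9:
        raise BridgeEdgeError(
            f"edge {e} is a bridge; its outage disconnects the network")
    dF = eta_col * (flow.flows[e] / denom)
    dF[e] = -flow.flows[e]
    return dF


def edge_distance_matrix(graph: PlaneGraph) -> np.ndarray:
    """Unweighted edge-to-edge distances (M x M).

    The distance between two edges is the minimum hop count over their
    endpoint pairs: edges sharing a node are at distance 0.  Hops are
    unweighted so the distance binning stays fixed while edge weights are
    scanned.  Unreachable pairs get distance -1.
    """
    n = graph.n_nodes
    adj = graph.adjacency()
    unreach = 4 * n + 4
    dist = np.full((n, n), unreach, dtype=np.int64)
    for s in range(n):
        dist[s, s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            i = queue[head]
            head += 1
            for j, _ in adj[i]:
                if dist[s, j] > dist[s, i] + 1:
                    dist[s, j] = dist[s, i] + 1
                    queue.append(j)
    iu, iv = graph.edges[:, 0], graph.edges[:, 1]
    d = np.minimum(
        np.minimum(dist[np.ix_(iu, iu)], dist[np.ix_(iu, iv)]),
        np.minimum(dist[np.ix_(iv, iu)], dist[np.ix_(iv, iv)]),
    )
    d[d >= unreach] = -1
    return d


def edge_communities_from_nodes(graph: PlaneGraph, community1,
                                community2) -> np.ndarray:
    """Assign each edge to a primal community: 0/1 if both endpoints lie in
    the community, -1 for boundary edges (in neither)."""
    c1, c2 = set(community1), set(community2)
    lab = np.full(graph.n_edges, -1, dtype=np.int64)
    for k, (iu, iv) in enumerate(graph.edges):
        u, v = graph.nodes[iu], graph.nodes[iv]
        if u in c1 and v in c1:
            lab[k] = 0
        elif u in c2 and v in c2:
            lab[k] = 1
    return lab


def edge_communities_from_faces(dual: DualGraph, community1,
                                community2) -> np.ndarray:
    """Assign each primal edge to a dual community: 0/1 if every interior
    face it borders lies in the community, -1 for cut-path edges (shared by
    both sides).  Outer-boundary edges follow their single interior face."""
    graph = dual.primal
    c1, c2 = set(community1), set(community2)
    membership: list[list[int]] = [[] for _ in range(graph.n_edges)]
    for c, f in enumerate(dual.faces.faces):
        for eid in f.edge_ids:
            membership[eid].append(c)
    lab = np.full(graph.n_edges, -1, dtype=np.int64)
    for k, cycs in enumerate(membership):
        if not cycs:
            continue
        in1 = all(c in c1 for c in cycs)
        in2 = all(c in c2 for c in cycs)
        if in1:
            lab[k] = 0
        elif in2:
            lab[k] = 1
    return lab


def flow_ratio_scan(nx_: int = 21, ny_: int = 10, weights=None) -> pd.DataFrame:
    """Mean flow ratio R of a square lattice versus boundary weight.

    Boundary weights below one weaken the crossing edges (primal
    communities, community assignment by nodes); weights above one
    strengthen the central column (dual communities, assignment by faces).
    Returns a DataFrame with columns w, R, lambda2, lambda2_star.
    """
    from .communities import fiedler
    from .graph import laplacian
    from .dual import build_dual, dual_laplacian
    from .synth import square_lattice

    if weights is None:
        weights = np.logspace(-3, 3, 7)
    rows = []
    for w in weights:
        mode = "cut_set" if w <= 1 else "cut_path"
        lat = square_lattice(nx_, ny_, mode, float(w))
        g = lat.graph
        if mode == "cut_set":
            labels = edge_communities_from_nodes(g, lat.left_nodes,
                                                 lat.right_nodes)
        else:
            dual = build_dual(g)
            left = [c for c in range(dual.n_nodes)
                    if dual.coords[c, 0] < lat.split_x]
            right = [c for c in range(dual.n_nodes)
                     if dual.coords[c, 0] >= lat.split_x]
            labels = edge_communities_from_faces(dual, left, right)
        R = flow_ratio(g, labels).mean_ratio
        rows.append({"w": float(w), "R": R,
                     "lambda2": fiedler(laplacian(g))[0],
                     "lambda2_star": fiedler(dual_laplacian(g))[0]})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FlowRatioResult:
    """Mean flow ratio R and the per-(trigger edge, distance) table."""

    mean_ratio: float
    table: pd.DataFrame      # columns: edge, distance, ratio

    def __float__(self) -> float:
        return self.mean_ratio


def flow_ratio(graph: PlaneGraph, edge_labels: np.ndarray,
               eta: np.ndarray | None = None,
               distances: np.ndarray | None = None) -> FlowRatioResult:
    """Community flow ratio ``R`` for a two-community edge partition.

    For every trigger edge ``e`` inside a community and every distance ``d``,
    ``R(e, d)`` is the mean |eta| over other-community edges at distance
    ``d`` divided by the mean |eta| over same-community edges at distance
    ``d``; pairs where either average is undefined are skipped.  ``R`` is the
    plain mean of all defined ``R(e, d)``.

    Parameters
    ----------
    edge_labels : array of {0, 1, -1}
        Community per edge; -1 marks boundary edges (never triggers, never
        counted in either average).
    """
    if eta is None:
        eta = sensitivity_matrix(graph)
    if distances is None:
        distances = edge_distance_matrix(graph)
    absn = np.abs(eta)
    rows = []
    max_d = int(distances.max())
    for e in range(graph.n_edges):
        ce = edge_labels[e]
        if ce < 0:
            continue
        same = (edge_labels == ce) & (distances[e] >= 0)
        other = (edge_labels == 1 - ce) & (distances[e] >= 0)
        same[e] = False
        for d in range(max_d + 1):
            at_d = distances[e] == d
            s_mask = same & at_d
            o_mask = other & at_d
            if not s_mask.any() or not o_mask.any():
                continue
            denom = absn[s_mask, e].mean()
            if denom == 0:
                continue
            rows.append((e, d, absn[o_mask, e].mean() / denom))
    table = pd.DataFrame(rows, columns=["edge", "distance", "ratio"])
    mean_ratio = float(table["ratio"].mean()) if len(table) else 0.0
    return FlowRatioResult(mean_ratio, table)
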