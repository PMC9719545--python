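"""Faces, cycle space and the weighted dual graph.

For a plane graph the interior faces span the cycle space (dimension
``M - N + 1``).  Writing their boundary cycles into a signed cycle-edge
incidence matrix ``C`` turns Kirchhoff's voltage law into a discrete Poisson
equation with the *dual Laplacian* ``L* = C^T W^{-1} C``: a Laplacian on the
graph whose nodes are the faces.  Two faces are joined by a dual edge when
they share primal edges, and the dual weight is the summed *inverse* primal
weight, ``w*_{c,d} = sum_l 1/w_l`` — strong primal connections are weak dual
ones and vice versa.  Parallel dual edges are lumped (reduced dual graph).

Face enumeration uses the rotation system induced by the plane coordinates
(counter-clockwise angular order of incident edges); interior faces are
traversed counter-clockwise, and the outer face is recognised by its negative
signed area.

For non-planar graphs an algebraic dual can be built from any cycle basis
(:func:`dual_from_cycle_basis`), typically a minimum cycle basis.  The dual
then depends on the basis choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import networkx as nx

from .graph import PlaneGraph, GraphError, build_incidence

__all__ = [
    "Face",
    "FaceSet",
    "DualGraph",
    "EmbeddingError",
    "enumerate_faces",
    "cycle_incidence",
    "build_dual",
    "dual_laplacian",
    "dual_from_cycle_basis",
]


class EmbeddingError(GraphError):
    """The plane embedding is inconsistent (face traversal failed)."""


@dataclass(frozen=True)
class Face:
    """One face: cyclic node sequence and oriented boundary edges.

    ``oriented_edges`` holds (edge index, sign) pairs; the sign is +1 when the
    stored edge orientation agrees with the face traversal direction.
    """

    nodes: tuple
    oriented_edges: tuple  # of (edge_id, sign)
    area: float

    @property
    def edge_ids(self) -> tuple:
        return tuple(e for e, _ in self.oriented_edges)


@dataclass(frozen=True)
class FaceSet:
    """Interior faces of a plane graph plus the identified outer face."""

    graph: PlaneGraph
    faces: tuple          # interior faces, counter-clockwise
    outer: Face

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def centroid(self, c: int) -> np.ndarray:
        idx = [self.graph.node_index(n) for n in self.faces[c].nodes]
        return self.graph.coords[idx].mean(axis=0)


def _rotation_system(graph: PlaneGraph) -> list[list[int]]:
    """Counter-clockwise cyclic order of neighbour indices at each node."""
    order: list[list[int]] = []
    adj = graph.adjacency()
    for i in range(graph.n_nodes):
        nbrs = [j for j, _ in adj[i]]
        ang = [math.atan2(graph.coords[j][1] - graph.coords[i][1],
                          graph.coords[j][0] - graph.coords[i][0]) for j in nbrs]
        order.append([j for _, j in sorted(zip(ang, nbrs))])
    return order


def enumerate_faces(graph: PlaneGraph) -> FaceSet:
    """Enumerate the faces of a plane graph from its rotation system.

    Every directed half-edge belongs to exactly one face; the traversal rule
    "after arriving at v from u, leave along the clockwise-next edge after
    (v,u)" produces interior faces counter-clockwise.  The face of maximal
    negative signed area is the outer face and is excluded.

    Raises
    ------
    EmbeddingError
        If the interior face count differs from ``M - N + 1`` (non-planar
        drawing or inconsistent embedding).
    """
    rot = _rotation_system(graph)
    pos_in_rot = [
        {j: p for p, j in enumerate(rot[i])} for i in range(graph.n_nodes)
    ]
    visited: set[tuple[int, int]] = set()
    faces: list[Face] = []
    P = graph.coords

    for k, (a, b) in enumerate(graph.edges):
        for u0, v0 in ((a, b), (b, a)):
            if (u0, v0) in visited:
                continue
            cycle_nodes: list[int] = []
            cycle_edges: list[tuple[int, int]] = []
            u, v = u0, v0
            while True:
                visited.add((u, v))
                cycle_nodes.append(u)
                eid = graph._edge_index[(u, v) if u < v else (v, u)]
                cycle_edges.append((eid, 1 if u < v else -1))
                # predecessor of u in the ccw order at v = clockwise-next
                r = rot[v]
                w = r[(pos_in_rot[v][u] - 1) % len(r)]
                u, v = v, w
                if (u, v) == (u0, v0):
                    break
                if len(cycle_nodes) > 2 * graph.n_edges + 1:
                    raise EmbeddingError("face traversal did not close")
            area = 0.0
            for i in range(len(cycle_nodes)):
                x1, y1 = P[cycle_nodes[i]]
                x2, y2 = P[cycle_nodes[(i + 1) % len(cycle_nodes)]]
                area += x1 * y2 - x2 * y1
            faces.append(Face(
                nodes=tuple(graph.nodes[i] for i in cycle_nodes),
                oriented_edges=tuple(cycle_edges),
                area=0.5 * area,
            ))

    outer_idx = int(np.argmin([f.area for f in faces]))
    outer = faces.pop(outer_idx)
    expected = graph.n_edges - graph.n_nodes + 1
    if len(faces) != expected:
        raise EmbeddingError(
            f"found {len(faces)} interior faces, expected M-N+1={expected}; "
            "the drawing is not a valid plane embedding")
    faces.sort(key=lambda f: min(f.edge_ids))  # deterministic face order
    return FaceSet(graph=graph, faces=tuple(faces), outer=outer)


def cycle_incidence(faces: FaceSet | Sequence[Sequence[tuple[int, int]]],
                    n_edges: int | None = None) -> np.ndarray:
    """Signed cycle-edge incidence matrix C (M x number of cycles).

    Column ``c`` is the oriented boundary cycle of face ``c``; every column is
    a valid cycle flow, i.e. ``I^T C = 0`` exactly.
    """
    if isinstance(faces, FaceSet):
        cols = [f.oriented_edges for f in faces.faces]
        n_edges = faces.graph.n_edges
    else:
        cols = list(faces)
        if n_edges is None:
            raise ValueError("n_edges required for raw cycle lists")
    C = np.zeros((n_edges, len(cols)))
    for c, oriented in enumerate(cols):
        for eid, sign in oriented:
            C[eid, c] += sign
    return C


@dataclass(frozen=True)
class DualGraph:
    """Reduced weighted dual graph of a plane graph (or of a cycle basis).

    Nodes are the interior faces (basis cycles); an edge joins two faces
    sharing at least one primal edge and carries weight
    ``w* = sum over shared edges of 1/w``.  The map back to the shared primal
    edges is retained, which is what turns a dual bisection into a primal
    cut-path.
    """

    primal: PlaneGraph
    n_nodes: int
    edges: tuple            # (c, d) pairs, c < d
    weights: np.ndarray     # dual weights w*
    shared: dict            # (c, d) -> tuple of primal edge ids
    coords: np.ndarray      # face centroids, for plotting/serialisation
    faces: FaceSet | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def laplacian(self) -> np.ndarray:
        L = np.zeros((self.n_nodes, self.n_nodes))
        for (c, d), w in zip(self.edges, self.weights):
            L[c, c] += w
            L[d, d] += w
            L[c, d] -= w
            L[d, c] -= w
        return L

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for c, d in self.edges:
            adj[c].append(d)
            adj[d].append(c)
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_nodes

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for c in range(self.n_nodes):
            G.add_node(c, pos=tuple(self.coords[c]))
        for (c, d), w, in zip(self.edges, self.weights):
            G.add_edge(c, d, weight=float(w),
                       shared=list(map(int, self.shared[(c, d)])))
        return G


def _dual_from_membership(graph: PlaneGraph, membership: list[list[int]],
                          n_cycles: int, centroids: np.ndarray,
                          faces: FaceSet | None,
                          allow_multi: bool = False) -> DualGraph:
    """Assemble the reduced dual given, per primal edge, the cycles using it."""
    shared: dict[tuple[int, int], list[int]] = {}
    for eid, cycs in enumerate(membership):
        if len(cycs) == 2:
            c, d = sorted(cycs)
            shared.setdefault((c, d), []).append(eid)
        elif len(cycs) > 2:
            if not allow_multi:
                raise GraphError(
                    f"edge {eid} lies on {len(cycs)} cycles; not a valid face set")
            for a in range(len(cycs)):
                for b in range(a + 1, len(cycs)):
                    c, d = sorted((cycs[a], cycs[b]))
                    shared.setdefault((c, d), []).append(eid)
    pairs = sorted(shared)
    weights = np.array([sum(1.0 / graph.weights[e] for e in shared[p])
                        for p in pairs])
    dual = DualGraph(
        primal=graph,
        n_nodes=n_cycles,
        edges=tuple(pairs),
        weights=weights,
        shared={p: tuple(shared[p]) for p in pairs},
        coords=centroids,
        faces=faces,
    )
    return dual


def build_dual(graph: PlaneGraph, faces: FaceSet | None = None) -> DualGraph:
    """Construct the reduced dual graph of a plane graph.

    Raises
    ------
    GraphError
        If the graph has fewer than two interior faces (degenerate dual).
    """
    if faces is None:
        faces = enumerate_faces(graph)
    if faces.n_faces < 2:
        raise GraphError("dual graph needs at least two interior faces")
    membership: list[list[int]] = [[] for _ in range(graph.n_edges)]
    for c, f in enumerate(faces.faces):
        for eid in f.edge_ids:
            membership[eid].append(c)
    centroids = np.array([faces.centroid(c) for c in range(faces.n_faces)])
    return _dual_from_membership(graph, membership, faces.n_faces,
                                 centroids, faces)


def dual_laplacian(graph: PlaneGraph, faces: FaceSet | None = None) -> np.ndarray:
    """Laplacian of the reduced dual graph, ``(M-N+1) x (M-N+1)``.

    Equals ``C^T W^{-1} C`` with the cycle-edge incidence matrix restricted
    to the edges shared by two *interior* faces — the adjustment the reduced
    dual requires: edges on the outer boundary belong to no dual edge, so
    they contribute neither to off-diagonals nor to the weighted dual
    degrees.  (The unrestricted ``C`` of :func:`cycle_incidence` is the
    cycle-space object used by Kirchhoff's voltage law and the dual
    sensitivity formula; its ``C^T W^{-1} C`` is the same matrix plus the
    diagonal of outer-boundary terms.)
    """
    if faces is None:
        faces = enumerate_faces(graph)
    return build_dual(graph, faces).laplacian()


def _order_cycle(graph: PlaneGraph, nodes: set) -> list:
    """Order a cycle's node set into a traversal, deterministically.

    Requires the induced edge set to be a single chordless cycle (every node
    of degree two within the set); raises otherwise.
    """
    nbrs: dict = {n: [] for n in nodes}
    for iu, iv in graph.edges:
        u, v = graph.nodes[iu], graph.nodes[iv]
        if u in nbrs and v in nbrs:
            nbrs[u].append(v)
            nbrs[v].append(u)
    if any(len(v) != 2 for v in nbrs.values()):
        raise GraphError(
            "cycle basis element is not a chordless cycle; "
            "provide ordered cycles explicitly")
    start = min(nodes)
    nxt = min(nbrs[start])  # deterministic direction
    order = [start, nxt]
    while order[-1] != start:
        a, b = nbrs[order[-1]]
        order.append(b if a == order[-2] else a)
    return order[:-1]


def dual_from_cycle_basis(graph: PlaneGraph,
                          basis: Sequence[Sequence] | None = None) -> DualGraph:
    """Algebraic dual from a cycle basis (planarity not required).

    Parameters
    ----------
    basis : sequence of node sequences, optional
        Each entry is a cycle given by its nodes (ordered or not).  When
        omitted, the graph's minimum cycle basis is computed with unit edge
        lengths (fewest-edge cycles); ties are resolved by networkx's
        deterministic traversal order, and unordered basis cycles must be
        chordless (node lists do not identify the edge set otherwise).

    Notes
    -----
    Different bases yield different duals; the face basis of a plane graph
    reproduces :func:`build_dual`.
    """
    if basis is None:
        G = graph.to_networkx()
        basis = nx.minimum_cycle_basis(G)
        basis = sorted((sorted(c) for c in basis), key=lambda c: (len(c), c))
    expected = graph.n_edges - graph.n_nodes + 1
    if len(basis) != expected:
        raise GraphError(
            f"basis has {len(basis)} cycles, expected M-N+1={expected}")

    I = build_incidence(graph)
    cycles: list[list[tuple[int, int]]] = []
    for cyc in basis:
        nodes = list(cyc)
        if len(set(nodes)) != len(nodes):
            raise GraphError("cycle contains repeated nodes")
        ordered = nodes if _is_ordered_cycle(graph, nodes) else \
            _order_cycle(graph, set(nodes))
        oriented = []
        for i, u in enumerate(ordered):
            v = ordered[(i + 1) % len(ordered)]
            eid = graph.edge_index(u, v)
            sign = 1 if graph.node_index(u) < graph.node_index(v) else -1
            oriented.append((eid, sign))
        cycles.append(oriented)

    C = cycle_incidence(cycles, n_edges=graph.n_edges)
    if np.abs(I.T @ C).max() > 0:
        raise GraphError("invalid basis: I^T C != 0")

    membership: list[list[int]] = [[] for _ in range(graph.n_edges)]
    for c, oriented in enumerate(cycles):
        for eid, _ in oriented:
            membership[eid].append(c)
    centroids = np.array([
        graph.coords[[graph.node_index(n) for n in cyc]].mean(axis=0)
        if len(cyc) else (np.nan, np.nan)
        for cyc in basis
    ])
    return _dual_from_membership(graph, membership, len(basis),
                                 centroids, None, allow_multi=True)


def _is_ordered_cycle(graph: PlaneGraph, nodes: list) -> bool:
    return all(
        graph.has_edge(nodes[i], nodes[(i + 1) % len(nodes)])
        for i in range(len(nodes))
    )
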