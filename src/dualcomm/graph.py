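"""Primal plane-graph data model and linear flow solution.

A :class:`PlaneGraph` is a connected, simple, weighted undirected graph drawn
in the plane: every node carries 2D coordinates and every edge a strictly
positive weight (a conductivity).  Each edge has a fixed orientation (from the
lower-indexed to the higher-indexed node) which downstream sign conventions
inherit: the oriented incidence matrix, cycle–edge incidence matrices and
sensitivity factors all refer to it.

Linear flow networks on such graphs obey ``F = W I theta`` together with node
balance ``I^T F = P`` (Kirchhoff's current law), so the potentials solve the
discrete Poisson equation ``L theta = P`` with ``L = I^T W I`` the weighted
graph Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.sparse.linalg import LinearOperator, cg

NodeId = Hashable

__all__ = [
    "PlaneGraph",
    "FlowState",
    "GraphError",
    "UnbalancedInjectionError",
    "DisconnectedError",
    "build_incidence",
    "laplacian",
    "laplacian_pinv",
    "solve_flow",
]


class GraphError(ValueError):
    """Invalid graph construction or use."""


class UnbalancedInjectionError(GraphError):
    """Injection vector does not sum to zero."""


class DisconnectedError(GraphError):
    """Operation requires a connected graph."""


@dataclass(frozen=True)
class PlaneGraph:
    """Weighted plane graph with node coordinates and fixed edge orientations.

    Parameters
    ----------
    nodes : list
        Node identifiers, sorted; index into ``coords``.
    coords : ndarray, shape (N, 2)
        Plane coordinates of the nodes (dimensionless).
    edges : ndarray, shape (M, 2)
        Integer node indices per edge, oriented low index -> high index.
    weights : ndarray, shape (M,)
        Strictly positive edge weights (conductivities).
    """

    nodes: tuple
    coords: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)
    _edge_index: dict = field(repr=False, default_factory=dict)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_edgelist(
        cls,
        edges: Iterable[tuple[NodeId, NodeId]],
        coords: Mapping[NodeId, tuple[float, float]],
        weights: Iterable[float] | Mapping[tuple[NodeId, NodeId], float] | None = None,
        check: bool = True,
    ) -> "PlaneGraph":
        """Build a plane graph from (u, v) pairs, coordinates and weights.

        Edge orientation is canonicalised to (min, max) in the sorted node
        order regardless of the order in which endpoints are given.
        """
        edges = list(edges)
        if isinstance(weights, Mapping):
            wlist = []
            for u, v in edges:
                if (u, v) in weights:
                    wlist.append(weights[(u, v)])
                elif (v, u) in weights:
                    wlist.append(weights[(v, u)])
                else:
                    raise GraphError(f"missing weight for edge {(u, v)}")
        elif weights is None:
            wlist = [1.0] * len(edges)
        else:
            wlist = list(weights)
            if len(wlist) != len(edges):
                raise GraphError("weights length does not match edges")

        node_ids = sorted(coords)
        index = {n: i for i, n in enumerate(node_ids)}
        coord_arr = np.asarray([coords[n] for n in node_ids], dtype=float)
        if coord_arr.ndim != 2 or coord_arr.shape[1] != 2:
            raise GraphError("coordinates must be 2D")

        eidx = np.empty((len(edges), 2), dtype=np.int64)
        warr = np.asarray(wlist, dtype=float)
        seen: dict[tuple[int, int], int] = {}
        for k, (u, v) in enumerate(edges):
            try:
                iu, iv = index[u], index[v]
            except KeyError as exc:
                raise GraphError(f"edge endpoint {exc} has no coordinates") from exc
            if iu == iv:
                raise GraphError(f"self-loop at node {u}")
            if iu > iv:
                iu, iv = iv, iu
            if (iu, iv) in seen:
                raise GraphError(f"duplicate edge {(u, v)}")
            seen[(iu, iv)] = k
            eidx[k] = (iu, iv)

        g = cls(
            nodes=tuple(node_ids),
            coords=coord_arr,
            edges=eidx,
            weights=warr,
            _index=index,
            _edge_index={e: k for e, k in seen.items()},
        )
        if check:
            g.validate()
        return g

    @classmethod
    def from_networkx(cls, G: nx.Graph, pos: Mapping | None = None,
                      weight: str = "weight") -> "PlaneGraph":
        """Convert a networkx graph; coordinates come from ``pos`` or the
        node attribute ``pos``."""
        if pos is None:
            pos = nx.get_node_attributes(G, "pos")
            if len(pos) != G.number_of_nodes():
                raise GraphError("all nodes need a 'pos' attribute or explicit pos")
        coords = {n: tuple(map(float, pos[n])) for n in G.nodes}
        edges = list(G.edges())
        weights = [float(G.edges[e].get(weight, 1.0)) for e in edges]
        return cls.from_edgelist(edges, coords, weights)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for i, n in enumerate(self.nodes):
            G.add_node(n, pos=tuple(self.coords[i]))
        for k, (iu, iv) in enumerate(self.edges):
            G.add_edge(self.nodes[iu], self.nodes[iv], weight=float(self.weights[k]))
        return G

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, n: NodeId) -> int:
        return self._index[n]

    def edge_nodes(self, k: int) -> tuple[NodeId, NodeId]:
        """Oriented endpoints (start, end) of edge ``k``."""
        iu, iv = self.edges[k]
        return self.nodes[iu], self.nodes[iv]

    def edge_index(self, u: NodeId, v: NodeId) -> int:
        iu, iv = self._index[u], self._index[v]
        if iu > iv:
            iu, iv = iv, iu
        try:
            return self._edge_index[(iu, iv)]
        except KeyError as exc:
            raise GraphError(f"no edge between {u} and {v}") from exc

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        iu, iv = self._index[u], self._index[v]
        if iu > iv:
            iu, iv = iv, iu
        return (iu, iv) in self._edge_index

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per node index: list of (neighbour index, edge index)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for k, (iu, iv) in enumerate(self.edges):
            adj[iu].append((iv, k))
            adj[iv].append((iu, k))
        return adj

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self, check_planarity: bool = False) -> None:
        """Check invariants: positive finite weights, connectivity and, on
        demand, that the straight-line drawing has no crossing edges."""
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise GraphError("edge weights must be strictly positive and finite")
        if not np.all(np.isfinite(self.coords)):
            raise GraphError("coordinates must be finite")
        if self.n_nodes and not self.is_connected():
            raise DisconnectedError("graph is not connected")
        if check_planarity and self._has_crossing():
            raise GraphError("straight-line drawing has crossing edges")

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        adj = self.adjacency()
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j, _ in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        return bool(seen.all())

    def _has_crossing(self) -> bool:
        # O(M^2) segment intersection test; fixtures are desk-scale.
        P = self.coords

        def orient(a, b, c):
            return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

        E = self.edges
        for a in range(len(E)):
            for b in range(a + 1, len(E)):
                i, j = E[a]
                k, l = E[b]
                if len({i, j, k, l}) < 4:
                    continue  # shared endpoint
                if (orient(P[i], P[j], P[k]) * orient(P[i], P[j], P[l]) < 0
                        and orient(P[k], P[l], P[i]) * orient(P[k], P[l], P[j]) < 0):
                    return True
        return False

    # ------------------------------------------------------------------
    # derived graphs
    # ------------------------------------------------------------------
    def with_weights(self, weights: np.ndarray) -> "PlaneGraph":
        """Same topology and embedding, new weights."""
        w = np.asarray(weights, dtype=float)
        if w.shape != self.weights.shape:
            raise GraphError("weight vector has wrong length")
        return PlaneGraph(self.nodes, self.coords, self.edges, w,
                          self._index, self._edge_index)

    def edge_subgraph(self, edge_ids: Sequence[int],
                      extra_nodes: Sequence[NodeId] = ()) -> "PlaneGraph":
        """Subgraph keeping the given edges (and their endpoints)."""
        edge_ids = sorted(set(int(k) for k in edge_ids))
        keep_nodes = {self.nodes[i] for k in edge_ids for i in self.edges[k]}
        keep_nodes.update(extra_nodes)
        coords = {n: tuple(self.coords[self._index[n]]) for n in keep_nodes}
        edges = [(self.nodes[self.edges[k][0]], self.nodes[self.edges[k][1]])
                 for k in edge_ids]
        return PlaneGraph.from_edgelist(edges, coords,
                                        [self.weights[k] for k in edge_ids],
                                        check=False)

    def induced_subgraph(self, node_ids: Iterable[NodeId]) -> "PlaneGraph":
        keep = set(node_ids)
        edge_ids = [k for k, (iu, iv) in enumerate(self.edges)
                    if self.nodes[iu] in keep and self.nodes[iv] in keep]
        return self.edge_subgraph(edge_ids, extra_nodes=keep)

    def connected_components(self) -> list[set]:
        adj = self.adjacency()
        seen = np.zeros(self.n_nodes, dtype=bool)
        comps = []
        for s in range(self.n_nodes):
            if seen[s]:
                continue
            comp = {self.nodes[s]}
            seen[s] = True
            stack = [s]
            while stack:
                i = stack.pop()
                for j, _ in adj[i]:
                    if not seen[j]:
                        seen[j] = True
                        comp.add(self.nodes[j])
                        stack.append(j)
            comps.append(comp)
        return comps


@dataclass(frozen=True)
class FlowState:
    """Solved linear flow: injections P, potentials theta, edge flows F."""

    graph: PlaneGraph
    injections: np.ndarray      # P, per node
    potentials: np.ndarray      # theta, per node (mean-zero gauge)
    flows: np.ndarray           # F, per edge, along the stored orientation

    def residual(self) -> float:
        """Max node-balance violation |I^T F - P|."""
        I = build_incidence(self.graph)
        return float(np.abs(I.T @ self.flows - self.injections).max())

    def dissipation(self) -> float:
        """Energy identity Sum_l F_l^2 / w_l (= theta^T L theta)."""
        return float(np.sum(self.flows**2 / self.graph.weights))


def build_incidence(graph: PlaneGraph) -> np.ndarray:
    """Oriented edge-node incidence matrix I (M x N).

    Row ``l`` has +1 at the start node and -1 at the end node of edge ``l``;
    the row order matches the edge/weight order.
    """
    I = np.zeros((graph.n_edges, graph.n_nodes))
    rows = np.arange(graph.n_edges)
    I[rows, graph.edges[:, 0]] = 1.0
    I[rows, graph.edges[:, 1]] = -1.0
    return I


def laplacian(graph: PlaneGraph) -> np.ndarray:
    """Weighted graph Laplacian L = I^T W I (N x N, symmetric PSD)."""
    L = np.zeros((graph.n_nodes, graph.n_nodes))
    for k, (iu, iv) in enumerate(graph.edges):
        w = graph.weights[k]
        L[iu, iu] += w
        L[iv, iv] += w
        L[iu, iv] -= w
        L[iv, iu] -= w
    return L


_DENSE_PINV_LIMIT = 2000


def laplacian_pinv(graph: PlaneGraph) -> np.ndarray:
    """Moore-Penrose pseudoinverse of the graph Laplacian.

    Dense for desk-scale graphs; for larger systems prefer
    :func:`solve_flow`, which uses conjugate gradients.
    """
    L = laplacian(graph)
    n = graph.n_nodes
    if not graph.is_connected():
        return np.linalg.pinv(L, hermitian=True)
    # deflate the constant null vector: (L + J/n)^-1 - J/n with J = 11^T
    J = np.full((n, n), 1.0 / n)
    return np.linalg.inv(L + J) - J


def _solve_poisson(graph: PlaneGraph, P: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Solve L theta = P with mean-zero gauge."""
    n = graph.n_nodes
    if n <= _DENSE_PINV_LIMIT:
        L = laplacian(graph)
        J = np.full((n, n), 1.0 / n)
        theta = np.linalg.solve(L + J, P)
    else:
        from scipy import sparse

        rows = np.concatenate([graph.edges[:, 0], graph.edges[:, 1]])
        cols = np.concatenate([graph.edges[:, 1], graph.edges[:, 0]])
        w = np.concatenate([graph.weights, graph.weights])
        A = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
        deg = np.asarray(A.sum(axis=1)).ravel()
        L = sparse.diags(deg) - A

        def matvec(x):
            return L @ x + x.mean()  # deflated operator

        op = LinearOperator((n, n), matvec=matvec)
        theta, info = cg(op, P, rtol=tol, atol=0.0, maxiter=10 * n)
        if info != 0:
            raise GraphError("conjugate-gradient Poisson solve did not converge")
    return theta - theta.mean()


def solve_flow(graph: PlaneGraph, P: np.ndarray | Mapping[NodeId, float],
               tol: float = 1e-9) -> FlowState:
    """Solve the linear flow problem for a balanced injection vector.

    Parameters
    ----------
    P : array or mapping
        Injection per node (mapping entries default to 0). Must sum to zero
        within ``tol`` relative to the injection scale.

    Returns
    -------
    FlowState with mean-zero potentials and flows ``F = W I theta``.
    """
    if isinstance(P, Mapping):
        vec = np.zeros(graph.n_nodes)
        for n, p in P.items():
            vec[graph.node_index(n)] = p
        P = vec
    P = np.asarray(P, dtype=float)
    if P.shape != (graph.n_nodes,):
        raise GraphError("injection vector has wrong length")
    scale = max(np.abs(P).max(), 1.0)
    if abs(P.sum()) > tol * scale:
        raise UnbalancedInjectionError(
            f"injections sum to {P.sum():.3e}, not zero")
    if not graph.is_connected():
        raise DisconnectedError("flow solve requires a connected graph")
    theta = _solve_poisson(graph, P)
    iu, iv = graph.edges[:, 0], graph.edges[:, 1]
    F = graph.weights * (theta[iu] - theta[iv])
    return FlowState(graph, P, theta, F)
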