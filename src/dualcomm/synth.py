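"""Synthetic plane-network generators for every experiment in the package.

All generators are pure functions of their arguments: reruns are
bit-identical, the produced graphs pass :meth:`PlaneGraph.validate`, and any
engineered boundary (cut-set, cut-path, vein hierarchy) is returned
explicitly as an edge list so tests never have to rediscover it.

Node identifiers are the integer grid coordinates ``(i, j)`` (column, row)
for square lattices and the networkx lattice labels for triangular and
honeycomb lattices; coordinates are the drawing positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .graph import PlaneGraph, GraphError

__all__ = [
    "LatticeResult",
    "VeinHierarchyResult",
    "TriangularResult",
    "square_lattice",
    "triangular_lattice",
    "honeycomb_lattice",
    "vein_hierarchy_lattice",
]


@dataclass(frozen=True)
class LatticeResult:
    """A generated lattice plus its engineered boundary."""

    graph: PlaneGraph
    boundary_edges: tuple       # edge ids of the reweighted boundary
    mode: str
    split_x: float              # geometric position of the boundary line

    @property
    def left_nodes(self) -> frozenset:
        g = self.graph
        return frozenset(n for i, n in enumerate(g.nodes)
                         if g.coords[i, 0] < self.split_x)

    @property
    def right_nodes(self) -> frozenset:
        return frozenset(self.graph.nodes) - self.left_nodes


def _square_edges(nx_: int, ny_: int):
    for i in range(nx_):
        for j in range(ny_):
            if i + 1 < nx_:
                yield ((i, j), (i + 1, j))
            if j + 1 < ny_:
                yield ((i, j), (i, j + 1))


def square_lattice(nx_: int, ny_: int, mode: str = "none",
                   boundary_weight: float = 1.0,
                   base_weight: float = 1.0) -> LatticeResult:
    """Square lattice of ``nx_ x ny_`` nodes with a tunable central boundary.

    Modes
    -----
    ``none``
        Homogeneous lattice (``boundary_weight`` ignored).
    ``cut_set``
        The horizontal edges crossing the central vertical line are set to
        ``boundary_weight`` (< 1 induces two primal communities).
    ``cut_path``
        The vertical edges along the central column are set to
        ``boundary_weight`` (> 1 is a strong vein inducing dual communities).
    """
    if nx_ < 2 or ny_ < 2:
        raise GraphError("lattice needs at least 2x2 nodes")
    if mode not in ("none", "cut_set", "cut_path"):
        raise GraphError(f"unknown mode {mode!r}")
    edges = list(_square_edges(nx_, ny_))
    coords = {(i, j): (float(i), float(j))
              for i in range(nx_) for j in range(ny_)}
    weights = [base_weight] * len(edges)
    boundary: list[int] = []
    if mode == "cut_set":
        cxl = (nx_ - 1) // 2          # crossing edges (cxl,j)-(cxl+1,j)
        split_x = cxl + 0.5
        for k, (a, b) in enumerate(edges):
            if a[1] == b[1] and a[0] == cxl and b[0] == cxl + 1:
                weights[k] = boundary_weight
                boundary.append(k)
    elif mode == "cut_path":
        cx = nx_ // 2                 # vein: vertical edges of column cx
        split_x = float(cx)
        for k, (a, b) in enumerate(edges):
            if a[0] == b[0] == cx:
                weights[k] = boundary_weight
                boundary.append(k)
    else:
        split_x = (nx_ - 1) / 2.0
    graph = PlaneGraph.from_edgelist(edges, coords, weights)
    return LatticeResult(graph, tuple(boundary), mode, split_x)


@dataclass(frozen=True)
class TriangularResult:
    """Triangular lattice with source/sink roles for the supply optimiser."""

    graph: PlaneGraph
    sources: tuple              # leftmost and rightmost node
    sinks: tuple

    @property
    def source_indices(self) -> tuple:
        return tuple(self.graph.node_index(s) for s in self.sources)


def triangular_lattice(m: int, n: int) -> TriangularResult:
    """Triangulated strip with sources at the leftmost and rightmost node.

    ``m`` rows and ``n`` columns in networkx's triangular-lattice
    parametrisation; all other nodes are sinks.
    """
    G = nx.triangular_lattice_graph(m, n, with_positions=True)
    pos = nx.get_node_attributes(G, "pos")
    graph = PlaneGraph.from_networkx(G, pos)
    order = sorted(graph.nodes, key=lambda nd: (pos[nd][0], pos[nd][1]))
    left, right = order[0], order[-1]
    sinks = tuple(nd for nd in graph.nodes if nd not in (left, right))
    return TriangularResult(graph, (left, right), sinks)


def honeycomb_lattice(m: int, n: int, mode: str = "none",
                      boundary_weight: float = 1.0) -> LatticeResult:
    """Honeycomb lattice with a central community boundary.

    ``cut_set`` weakens the edges crossing the central vertical line
    (primal communities); ``cut_path`` strengthens a zig-zag path of edges
    running along that line (dual communities).
    """
    G = nx.hexagonal_lattice_graph(m, n, with_positions=True)
    pos = nx.get_node_attributes(G, "pos")
    graph = PlaneGraph.from_networkx(G, pos)
    xs = graph.coords[:, 0]
    cx = 0.5 * (xs.min() + xs.max())
    weights = graph.weights.copy()
    boundary: list[int] = []
    if mode == "cut_set":
        for k in range(graph.n_edges):
            iu, iv = graph.edges[k]
            x1, x2 = graph.coords[iu, 0], graph.coords[iv, 0]
            if (x1 - cx) * (x2 - cx) < 0:
                weights[k] = boundary_weight
                boundary.append(k)
    elif mode == "cut_path":
        boundary = list(_center_path_edges(graph, cx))
        for k in boundary:
            weights[k] = boundary_weight
    elif mode != "none":
        raise GraphError(f"unknown mode {mode!r}")
    return LatticeResult(graph.with_weights(weights), tuple(sorted(boundary)),
                         mode, cx)


def _center_path_edges(graph: PlaneGraph, cx: float) -> list[int]:
    """Zig-zag path of edges hugging the vertical line x = cx, found as a
    horizontal-deviation-weighted shortest path from the bottommost to the
    topmost node of the central band."""
    G = graph.to_networkx()
    pos = {n: graph.coords[graph.node_index(n)] for n in graph.nodes}
    for u, v in G.edges:
        G.edges[u, v]["dev"] = (abs(pos[u][0] - cx) + abs(pos[v][0] - cx)) + 1e-3
    band = [n for n in graph.nodes if abs(pos[n][0] - cx) < 1.0]
    if not band:
        band = list(graph.nodes)
    bottom = min(band, key=lambda n: (pos[n][1], abs(pos[n][0] - cx)))
    top = max(band, key=lambda n: (pos[n][1], -abs(pos[n][0] - cx)))
    path = nx.shortest_path(G, bottom, top, weight="dev")
    return [graph.edge_index(path[i], path[i + 1])
            for i in range(len(path) - 1)]


@dataclass(frozen=True)
class VeinHierarchyResult:
    """Square lattice with nested strong veins and its ground-truth hierarchy.

    ``truth`` lists, per hierarchy leaf, the primal node set the leaf covers
    (adjacent blocks share their vein nodes, mirroring how dual-side
    decomposition assigns the cut-path's terminal nodes to both children).
    """

    graph: PlaneGraph
    levels: int
    vein_edges: dict            # level -> tuple of edge ids
    truth: tuple                # frozensets of node ids, one per leaf
    _meta: dict = field(default_factory=dict, repr=False)

    def truth_labels(self) -> dict:
        """Disjoint node -> block label assignment (vein nodes go to the
        right/top block), for partition-similarity scores."""
        vx, vy, levels = (self._meta[k] for k in ("vx", "vy", "levels"))
        labels = {}
        for (i, j) in self.graph.nodes:
            lab = 0 if i < vx else 1
            if levels >= 2:
                lab = 2 * lab + (0 if j < vy else 1)
            labels[(i, j)] = lab
        return labels


def vein_hierarchy_lattice(levels: int = 2, nx_: int = 13, ny_: int = 13,
                           c1: float = 1e3, c2: float = 1e2,
                           vx: int | None = None, vy: int | None = None,
                           base_weight: float = 1.0) -> VeinHierarchyResult:
    """Square lattice with a primary vein and a nested secondary vein.

    Level 1: the vertical edges of column ``vx`` get weight ``c1`` (the
    primary vein).  Level 2: the horizontal edges of row ``vy`` get weight
    ``c2 < c1`` (secondary veins in both blocks).  The veins sit off-centre
    by default (at one quarter of each dimension), as vein positions in real
    venation networks are set by the vasculature, not by the balanced cut a
    primal spectral bisection prefers.  The returned ground truth is the
    hierarchy of blocks the veins delimit (2 leaves for one level, 4 for
    two); adjacent blocks share their bounding vein nodes.
    """
    if levels not in (1, 2):
        raise GraphError("levels must be 1 or 2")
    if not (c1 > c2 > base_weight):
        raise GraphError("need c1 > c2 > base weight for a nested hierarchy")
    vx = nx_ // 4 if vx is None else vx
    vy = ny_ // 4 if vy is None else vy
    if not (0 < vx < nx_ - 1 and 0 < vy < ny_ - 1):
        raise GraphError("vein positions must be interior")
    edges = list(_square_edges(nx_, ny_))
    coords = {(i, j): (float(i), float(j))
              for i in range(nx_) for j in range(ny_)}
    weights = np.full(len(edges), float(base_weight))
    v1 = [k for k, (a, b) in enumerate(edges) if a[0] == b[0] == vx]
    weights[v1] = c1
    vein_edges = {1: tuple(v1)}
    if levels >= 2:
        v2 = [k for k, (a, b) in enumerate(edges) if a[1] == b[1] == vy]
        weights[v2] = c2
        vein_edges[2] = tuple(v2)

    graph = PlaneGraph.from_edgelist(edges, coords, weights)
    nodes = list(graph.nodes)
    if levels == 1:
        truth = (
            frozenset(n for n in nodes if n[0] <= vx),
            frozenset(n for n in nodes if n[0] >= vx),
        )
    else:
        truth = (
            frozenset(n for n in nodes if n[0] <= vx and n[1] <= vy),
            frozenset(n for n in nodes if n[0] <= vx and n[1] >= vy),
            frozenset(n for n in nodes if n[0] >= vx and n[1] <= vy),
            frozenset(n for n in nodes if n[0] >= vx and n[1] >= vy),
        )
    return VeinHierarchyResult(graph, levels, vein_edges, truth,
                               {"vx": vx, "vy": vy, "nx": nx_, "ny": ny_,
                                "levels": levels})
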