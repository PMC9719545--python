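"""Spectral bisection, connectivity bounds and hierarchical decomposition.

Communities are read off the Fiedler vector: the eigenvector ``v2`` of the
second-smallest Laplacian eigenvalue ``lambda_2`` (the algebraic
connectivity).  Nodes with ``v2_i > h`` form one community, the rest the
other (threshold ``h = 0`` by default).  The same construction applied to
the dual Laplacian yields *dual communities*: groups of faces separated by a
strongly weighted primal path rather than by a weak cut.

Two topological quantities bound the algebraic connectivities:

* cut-set bound      ``lambda_2  <= mu_2  = (N1+N2)/(N1*N2) * sum_{l in S} w_l``
* cut-path bound     ``lambda_2* <= mu_2* = (N1*+N2*)/(N1* N2*) * sum_{l in p} 1/w_l``

where ``S`` contains the primal edges between the two node communities and
``p`` the primal edges shared by faces of different dual communities.  Both
bounds become exact as the corresponding connectivity vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .graph import PlaneGraph, GraphError, DisconnectedError, laplacian
from .dual import DualGraph, build_dual, enumerate_faces

__all__ = [
    "Bisection",
    "HierarchyNode",
    "fiedler",
    "bisect",
    "cut_set",
    "cut_path",
    "hierarchical_decompose",
]

_DENSE_EIG_LIMIT = 500


def fiedler(L: np.ndarray, tol: float = 1e-12) -> tuple[float, np.ndarray]:
    """Second-smallest eigenpair of a connected graph's Laplacian.

    The eigenvector is normalised and its sign fixed so that the first entry
    of magnitude above ``1e-12`` is positive, which makes repeated runs (and
    different eigensolvers) return identical bisections.

    Raises
    ------
    DisconnectedError
        If ``lambda_2`` is numerically zero relative to the mean weighted
        degree (two or more components).
    """
    L = np.asarray(L)
    n = L.shape[0]
    if n < 2:
        raise GraphError("Fiedler pair needs at least two nodes")
    scale = max(np.trace(L) / n, 1e-300)
    if n <= _DENSE_EIG_LIMIT:
        vals, vecs = scipy.linalg.eigh(L, subset_by_index=(1, 1))
        lam2, v2 = float(vals[0]), vecs[:, 0]
    else:
        # deflate the constant mode, then shift-invert for the smallest pair
        c = 2.0 * float(L.diagonal().max())
        Ls = scipy.sparse.csr_matrix(L) if not scipy.sparse.issparse(L) else L

        ones = np.ones(n) / np.sqrt(n)

        def mv(x):
            return Ls @ x + c * ones * (ones @ x)

        op = scipy.sparse.linalg.LinearOperator((n, n), matvec=mv)
        v0 = np.cos(np.arange(n))  # deterministic start vector
        vals, vecs = scipy.sparse.linalg.eigsh(op, k=1, sigma=None, which="SA",
                                               v0=v0, tol=1e-10)
        lam2, v2 = float(vals[0]), vecs[:, 0]
        v2 = v2 - v2.mean()
        v2 /= np.linalg.norm(v2)
    if lam2 < 1e-12 * scale:
        raise DisconnectedError("lambda_2 ~ 0: graph is (numerically) disconnected")
    nz = np.flatnonzero(np.abs(v2) > 1e-12)
    if nz.size and v2[nz[0]] < 0:
        v2 = -v2
    return lam2, v2


@dataclass
class Bisection:
    """A two-community spectral split with its boundary and bound.

    ``side`` is "primal" (communities are node sets, boundary a cut-set) or
    "dual" (communities are face-index sets, boundary a cut-path of primal
    edges).  ``mu2`` is the topological connectivity bounding ``lam2``.
    """

    side: Literal["primal", "dual"]
    community1: frozenset
    community2: frozenset
    lam2: float
    fiedler_vector: np.ndarray
    threshold: float
    boundary_edges: tuple = ()          # primal edge ids
    mu2: float = float("nan")
    boundary_is_path: bool | None = None
    boundary_disconnects: bool | None = None
    terminal_nodes: frozenset = field(default_factory=frozenset)

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.community1), len(self.community2)


def _split_by_sign(values: np.ndarray, labels: Sequence, h: float):
    # ties (v2 == h) go to the first community, deterministically
    side1 = frozenset(l for l, x in zip(labels, values) if x - h >= 0)
    side2 = frozenset(l for l, x in zip(labels, values) if x - h < 0)
    if not side1 or not side2:
        raise GraphError("threshold produced a trivial (one-sided) split")
    return side1, side2


def bisect(graph_or_dual: PlaneGraph | DualGraph, h: float = 0.0) -> Bisection:
    """Spectral bisection of a primal graph or of a dual graph.

    Nodes are split by the sign of ``v2 - h`` (zero entries go to the
    non-positive side, deterministically).  The boundary (cut-set or
    cut-path) and its topological connectivity are attached.
    """
    if isinstance(graph_or_dual, DualGraph):
        dual = graph_or_dual
        lam2, v2 = fiedler(dual.laplacian())
        c1, c2 = _split_by_sign(v2, range(dual.n_nodes), h)
        bis = Bisection("dual", c1, c2, lam2, v2, h)
        cut_path(bis, dual)
        return bis
    graph = graph_or_dual
    lam2, v2 = fiedler(laplacian(graph))
    c1, c2 = _split_by_sign(v2, graph.nodes, h)
    bis = Bisection("primal", c1, c2, lam2, v2, h)
    cut_set(bis, graph)
    return bis


def cut_set(bisection: Bisection, graph: PlaneGraph) -> tuple[tuple, float]:
    """Cut-set of a primal bisection and its bound ``mu_2``.

    ``S`` holds the edges with endpoints in different communities;
    ``mu_2 = (N1+N2)/(N1*N2) * sum_{l in S} w_l`` upper-bounds ``lambda_2``.
    """
    if bisection.side != "primal":
        raise GraphError("cut_set applies to primal bisections")
    c1 = bisection.community1
    S = tuple(
        k for k, (iu, iv) in enumerate(graph.edges)
        if (graph.nodes[iu] in c1) != (graph.nodes[iv] in c1)
    )
    n1, n2 = bisection.sizes
    mu2 = (n1 + n2) / (n1 * n2) * float(graph.weights[list(S)].sum()) if S else 0.0
    bisection.boundary_edges = S
    bisection.mu2 = mu2
    removed = [k for k in range(graph.n_edges) if k not in set(S)]
    sub = graph.edge_subgraph(removed, extra_nodes=graph.nodes)
    bisection.boundary_disconnects = not sub.is_connected()
    return S, mu2


def cut_path(bisection: Bisection, dual: DualGraph) -> tuple[tuple, float]:
    """Cut-path of a dual bisection and its bound ``mu_2*``.

    The cut-path consists of the primal edges shared by faces from both dual
    communities, together with their terminal nodes; removing those nodes
    disconnects the primal graph.  ``mu_2* = (N1*+N2*)/(N1* N2*) *
    sum_{l in p} 1/w_l`` upper-bounds the dual Fiedler value.
    """
    if bisection.side != "dual":
        raise GraphError("cut_path applies to dual bisections")
    c1 = bisection.community1
    p: list[int] = []
    for (c, d), eids in dual.shared.items():
        if (c in c1) != (d in c1):
            p.extend(eids)
    p = tuple(sorted(set(p)))
    n1, n2 = bisection.sizes
    graph = dual.primal
    mu2 = ((n1 + n2) / (n1 * n2) *
           float(np.sum(1.0 / graph.weights[list(p)]))) if p else 0.0
    bisection.boundary_edges = p
    bisection.mu2 = mu2

    nodes_on_p: set = set()
    for k in p:
        u, v = graph.edge_nodes(k)
        nodes_on_p.update((u, v))
    bisection.terminal_nodes = frozenset(nodes_on_p)
    # does the shared-edge set form a single simple path?
    deg: dict = {}
    for k in p:
        u, v = graph.edge_nodes(k)
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    ends = [n for n, d in deg.items() if d == 1]
    sub = graph.edge_subgraph(p) if p else None
    bisection.boundary_is_path = bool(
        p and sub.is_connected() and len(ends) == 2
        and all(d <= 2 for d in deg.values()))
    # removal of the path's nodes must disconnect the primal graph
    remaining = [n for n in graph.nodes if n not in nodes_on_p]
    if remaining:
        sub2 = graph.induced_subgraph(remaining)
        comps = sub2.connected_components()
        bisection.boundary_disconnects = len(comps) > 1
    else:
        bisection.boundary_disconnects = False
    return p, mu2


@dataclass
class HierarchyNode:
    """Node of a hierarchical decomposition tree.

    Each internal node stores the bisection of its subgraph; children are the
    two community subgraphs with the boundary edges removed.  ``node_set`` is
    the set of primal nodes the branch covers (children of a dual split may
    share the cut-path's terminal nodes).
    """

    graph: PlaneGraph
    node_set: frozenset
    depth: int
    bisection: Bisection | None = None
    children: list = field(default_factory=list)
    face_set: frozenset | None = None   # dual side: face ids of this branch
    stop_reason: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["HierarchyNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_node_sets(self) -> list[frozenset]:
        return [l.node_set for l in self.leaves()]


def _primal_children(graph: PlaneGraph, bis: Bisection) -> list[PlaneGraph]:
    kids = []
    for comm in (bis.community1, bis.community2):
        kids.append(graph.induced_subgraph(comm))
    return kids


def _dual_children(graph: PlaneGraph, dual: DualGraph,
                   bis: Bisection) -> list[PlaneGraph]:
    """Community subgraphs of a dual split: the closure of each community's
    faces.

    Each child keeps every edge bounding one of its faces, *including* the
    cut-path edges: the path (a vein) is the shared boundary and belongs to
    both blocks, exactly as its terminal nodes do.  Inside a child the vein
    lies on the outer boundary, so it borders no pair of the child's faces
    and cannot be selected as a cut-path again."""
    kids = []
    for comm in (bis.community1, bis.community2):
        eids = set()
        for c in comm:
            eids.update(dual.faces.faces[c].edge_ids)
        kids.append(graph.edge_subgraph(sorted(eids)))
    return kids


def hierarchical_decompose(graph: PlaneGraph, m: int,
                           side: Literal["primal", "dual"] = "dual",
                           h: float = 0.0) -> HierarchyNode:
    """Repeated spectral bisection to depth ``m``.

    At every level the current primal subgraph is bisected (on its own
    Laplacian for ``side='primal'``; on the dual of its own embedding for
    ``side='dual'``), the boundary edges are removed, and the procedure
    recurses into the two community subgraphs.  Branches stop early (with a
    recorded reason) when a component has fewer than 4 nodes, is internally
    disconnected, or its dual has fewer than 2 faces.  Isolated nodes created
    by boundary removal are kept as singleton leaves.
    """
    if m < 1:
        raise GraphError("depth m must be >= 1")

    def rec(g: PlaneGraph, depth: int) -> HierarchyNode:
        node = HierarchyNode(graph=g, node_set=frozenset(g.nodes), depth=depth)
        if depth >= m:
            return node
        if g.n_nodes < 4:
            node.stop_reason = "fewer than 4 nodes"
            return node
        comps = g.connected_components()
        if len(comps) > 1:
            # boundary removal split the subgraph already: recurse per part
            for comp in sorted(comps, key=lambda c: sorted(map(str, c))):
                child = rec(g.induced_subgraph(comp), depth) \
                    if len(comp) > 1 else HierarchyNode(
                        graph=g.induced_subgraph(comp),
                        node_set=frozenset(comp), depth=depth,
                        stop_reason="singleton")
                node.children.append(child)
            return node
        try:
            if side == "primal":
                bis = bisect(g, h=h)
                kids = _primal_children(g, bis)
            else:
                faces = enumerate_faces(g)
                if faces.n_faces < 2:
                    node.stop_reason = "dual has fewer than 2 faces"
                    return node
                dual = build_dual(g, faces)
                bis = bisect(dual, h=h)
                kids = _dual_children(g, dual, bis)
                node.face_set = frozenset(range(faces.n_faces))
        except (GraphError, DisconnectedError) as exc:
            node.stop_reason = str(exc)
            return node
        node.bisection = bis
        for kid in kids:
            node.children.append(rec(kid, depth + 1))
        return node

    return rec(graph, 0)
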