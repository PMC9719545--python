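"""Serialisation of plane graphs and duals.

Three interchangeable formats:

* plain text: a weighted edge list (``u v w`` per line) plus a node
  coordinate file (``id x y`` per line);
* GraphML (via networkx) with ``weight`` edge attributes and ``x``/``y``
  node attributes;
* JSON: a single document with nodes, coordinates, edges and weights.

All readers validate weight positivity; node identifiers round-trip as
strings in the text formats (tuple ids are encoded as ``i,j``).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .graph import PlaneGraph, GraphError
from .dual import DualGraph

__all__ = [
    "write_edgelist", "read_edgelist",
    "write_graphml", "read_graphml",
    "to_json", "from_json", "write_json", "read_json",
    "dual_to_json",
]


def _encode_node(n) -> str:
    if isinstance(n, tuple):
        return ",".join(str(x) for x in n)
    return str(n)


def _decode_node(s: str):
    if "," in s:
        return tuple(int(x) if x.lstrip("-").isdigit() else float(x)
                     for x in s.split(","))
    if s.lstrip("-").isdigit():
        return int(s)
    return s


def write_edgelist(graph: PlaneGraph, edge_path, coord_path) -> None:
    """Write ``u v w`` lines and a companion ``id x y`` coordinate file."""
    with open(edge_path, "w") as fh:
        for k in range(graph.n_edges):
            u, v = graph.edge_nodes(k)
            fh.write(f"{_encode_node(u)} {_encode_node(v)} "
                     f"{float(graph.weights[k])!r}\n")
    with open(coord_path, "w") as fh:
        for i, n in enumerate(graph.nodes):
            x, y = graph.coords[i]
            fh.write(f"{_encode_node(n)} {float(x)!r} {float(y)!r}\n")


def read_edgelist(edge_path, coord_path) -> PlaneGraph:
    coords = {}
    for line in Path(coord_path).read_text().splitlines():
        if not line.strip():
            continue
        nid, x, y = line.split()
        coords[_decode_node(nid)] = (float(x), float(y))
    edges, weights = [], []
    for line in Path(edge_path).read_text().splitlines():
        if not line.strip():
            continue
        u, v, w = line.split()
        edges.append((_decode_node(u), _decode_node(v)))
        weights.append(float(w))
    if any(w <= 0 for w in weights):
        raise GraphError("edge weights must be positive")
    return PlaneGraph.from_edgelist(edges, coords, weights)


def write_graphml(graph: PlaneGraph, path) -> None:
    G = nx.Graph()
    for i, n in enumerate(graph.nodes):
        G.add_node(_encode_node(n), x=float(graph.coords[i, 0]),
                   y=float(graph.coords[i, 1]))
    for k in range(graph.n_edges):
        u, v = graph.edge_nodes(k)
        G.add_edge(_encode_node(u), _encode_node(v),
                   weight=float(graph.weights[k]))
    nx.write_graphml(G, path)


def read_graphml(path) -> PlaneGraph:
    G = nx.read_graphml(path)
    coords = {}
    for n, data in G.nodes(data=True):
        coords[_decode_node(n)] = (float(data["x"]), float(data["y"]))
    edges, weights = [], []
    for u, v, data in G.edges(data=True):
        edges.append((_decode_node(u), _decode_node(v)))
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise GraphError("edge weights must be positive")
        weights.append(w)
    return PlaneGraph.from_edgelist(edges, coords, weights)


def to_json(graph: PlaneGraph) -> dict:
    return {
        "nodes": [_encode_node(n) for n in graph.nodes],
        "coordinates": [[float(x), float(y)] for x, y in graph.coords],
        "edges": [[_encode_node(graph.edge_nodes(k)[0]),
                   _encode_node(graph.edge_nodes(k)[1])]
                  for k in range(graph.n_edges)],
        "weights": [float(w) for w in graph.weights],
    }


def from_json(doc: dict) -> PlaneGraph:
    nodes = [_decode_node(n) for n in doc["nodes"]]
    coords = {n: tuple(c) for n, c in zip(nodes, doc["coordinates"])}
    edges = [(_decode_node(u), _decode_node(v)) for u, v in doc["edges"]]
    weights = [float(w) for w in doc["weights"]]
    if any(w <= 0 for w in weights):
        raise GraphError("edge weights must be positive")
    return PlaneGraph.from_edgelist(edges, coords, weights)


def write_json(graph: PlaneGraph, path) -> None:
    Path(path).write_text(json.dumps(to_json(graph), indent=1))


def read_json(path) -> PlaneGraph:
    return from_json(json.loads(Path(path).read_text()))


def dual_to_json(dual: DualGraph) -> dict:
    """Serialise a dual graph: face nodes are indexed, coordinates are the
    face centroids, and each dual edge lists its shared primal edges."""
    return {
        "nodes": list(range(dual.n_nodes)),
        "coordinates": [[float(x), float(y)] for x, y in dual.coords],
        "edges": [[int(c), int(d)] for c, d in dual.edges],
        "weights": [float(w) for w in dual.weights],
        "shared_primal_edges": {f"{c}-{d}": [int(e) for e in dual.shared[(c, d)]]
                                for c, d in dual.edges},
    }
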