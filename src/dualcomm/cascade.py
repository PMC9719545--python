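"""Weighted threshold cascades and the boundary-blocking experiment.

Node states are binary (0 healthy / 1 faulty) and update synchronously: a
node becomes faulty when the *weighted average* of its neighbours' states
exceeds its threshold, and faulty nodes stay faulty::

    s_i(t+1) = 1   if  sum_k w_ik s_k / sum_k w_ik > phi_i   or   s_i(t) = 1

Because the dynamics are monotone the fixed point is reached in at most N
steps.

The boundary experiment seeds a fraction of the left half of a square
lattice and reweights (a random 80% of) the edges inside a central vertical
strip by a common factor ``w``.  A homogeneous lattice (w = 1) cascades
globally; both weak (w << 1) and strong (w >> 1) strips stop the cascade at
the boundary, for two different reasons: weak edges transmit too little
weight (leakage ~ w), while strong edges inflate the weighted-average
denominator of strip nodes (dilution ~ 1/w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .graph import PlaneGraph, GraphError
from .synth import square_lattice

__all__ = [
    "CascadeExperiment",
    "cascade_step",
    "run_cascade",
    "central_strip_edges",
    "run_replicate",
    "run_replicates",
    "cascade_scan",
]


def _weighted_adjacency(graph: PlaneGraph) -> sparse.csr_matrix:
    iu, iv = graph.edges[:, 0], graph.edges[:, 1]
    rows = np.concatenate([iu, iv])
    cols = np.concatenate([iv, iu])
    w = np.concatenate([graph.weights, graph.weights])
    return sparse.csr_matrix((w, (rows, cols)),
                             shape=(graph.n_nodes, graph.n_nodes))


def cascade_step(state: np.ndarray, graph: PlaneGraph,
                 thresholds: np.ndarray,
                 adjacency: sparse.csr_matrix | None = None) -> np.ndarray:
    """One synchronous update of the weighted threshold cascade."""
    if adjacency is None:
        adjacency = _weighted_adjacency(graph)
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    state = np.asarray(state, dtype=bool)
    return state | (adjacency @ state / deg > thresholds)


def run_cascade(state: np.ndarray, graph: PlaneGraph,
                thresholds: np.ndarray | float) -> tuple[np.ndarray, int]:
    """Iterate to the fixed point; returns (final state, number of steps)."""
    A = _weighted_adjacency(graph)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise GraphError("cascade requires every node to have an edge")
    phi = np.broadcast_to(np.asarray(thresholds, dtype=float),
                          (graph.n_nodes,))
    s = np.asarray(state, dtype=bool)
    steps = 0
    while True:
        new = s | (A @ s / deg > phi)
        if (new == s).all():
            return s, steps
        s = new
        steps += 1


@dataclass(frozen=True)
class CascadeExperiment:
    """Configuration of the central-strip blocking experiment.

    Defaults reproduce the blocked/global dichotomy on a desk-scale lattice:
    the strip is the ``strip_width`` central columns; the candidate edge set
    contains every edge with *both* endpoints in the strip (its vertical
    edges and the internal crossing layers), of which a random fraction
    ``p_e`` is reweighted to ``w`` per replicate.  Seeds are a random
    fraction ``rho0`` of the nodes left of the strip.
    """

    nx: int = 48
    ny: int = 20
    strip_width: int = 4
    p_e: float = 0.8
    rho0: float = 0.05
    phi: float = 0.18

    def __post_init__(self):
        if not 0 < self.p_e <= 1:
            raise GraphError("p_e must be in (0, 1]")
        if not 0 < self.rho0 < 1:
            raise GraphError("rho0 must be in (0, 1)")
        if self.strip_width < 1 or self.strip_width >= self.nx - 2:
            raise GraphError("strip width must fit inside the lattice")

    @property
    def strip_columns(self) -> range:
        start = (self.nx - self.strip_width) // 2
        return range(start, start + self.strip_width)


def central_strip_edges(graph: PlaneGraph, columns) -> np.ndarray:
    """Edge ids with both endpoints in the given lattice columns."""
    cols = set(columns)
    out = [k for k in range(graph.n_edges)
           if graph.edge_nodes(k)[0][0] in cols
           and graph.edge_nodes(k)[1][0] in cols]
    return np.asarray(out, dtype=np.int64)


def run_replicate(exp: CascadeExperiment, w: float,
                  rng: np.random.Generator) -> float:
    """One replicate: fresh boundary-edge subset and seed set; returns the
    final faulty fraction rho_infinity."""
    lat = square_lattice(exp.nx, exp.ny)
    graph = lat.graph
    cand = central_strip_edges(graph, exp.strip_columns)
    n_sel = int(round(exp.p_e * len(cand)))
    sel = rng.choice(cand, size=n_sel, replace=False)
    weights = graph.weights.copy()
    weights[sel] = w
    graph = graph.with_weights(weights)

    left = [n for n in graph.nodes if n[0] < min(exp.strip_columns)]
    n_seed = int(round(exp.rho0 * len(left)))
    seed_nodes = rng.choice(len(left), size=n_seed, replace=False)
    s0 = np.zeros(graph.n_nodes, dtype=bool)
    for i in seed_nodes:
        s0[graph.node_index(left[i])] = True

    final, _ = run_cascade(s0, graph, exp.phi)
    return float(final.mean())


def run_replicates(exp: CascadeExperiment, w: float, reps: int,
                   seed: int) -> np.ndarray:
    """Seeded ensemble of replicates for one strip weight ``w``."""
    rng = np.random.default_rng(seed)
    return np.array([run_replicate(exp, w, rng) for _ in range(reps)])


def cascade_scan(exp: CascadeExperiment, w_values, reps: int = 200,
                 seed: int = 0) -> pd.DataFrame:
    """Median and 25/75% quantiles of rho_infinity per strip weight.

    Each weight gets its own independent seeded replicate ensemble.
    """
    if reps < 2:
        raise GraphError("need at least 2 replicates")
    rows = []
    for i, w in enumerate(w_values):
        rhos = run_replicates(exp, float(w), reps, seed + i)
        q25, med, q75 = np.percentile(rhos, [25, 50, 75])
        rows.append({"w": float(w), "median": med, "q25": q25, "q75": q75,
                     "reps": reps})
    return pd.DataFrame(rows)
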