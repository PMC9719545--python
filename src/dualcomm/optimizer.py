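"""Optimal supply networks under fluctuating Dirichlet sources.

The model: a linear flow network whose sinks draw i.i.d. Gaussian outflows
``P_i ~ N(mu, sigma^2)`` and whose ``N_s`` sources balance the total demand
while sharing it according to a symmetric Dirichlet random vector
``X ~ Dir(alpha)`` scaled by ``K``::

    P_{s_a} = -(1/N_s) sum_sinks P_i + K (1/N_s - X_a)

The Dirichlet term adds source-only fluctuations of variance
``sigma_D^2 = K^2 (N_s - 1) / (N_s^2 (N_s alpha + 1))``: large ``alpha``
means calm sources, small ``alpha`` strongly anti-correlated ones.

Network design minimises the expected dissipation
``D = sum_l <F_l^2> / w_l`` subject to the resource constraint
``sum_l w_l^gamma <= 1`` (gamma < 1 favours sparse networks).  The
stationarity condition of the Lagrangian gives the classic fixed-point
rescaling ``w_l ~ <F_l^2>^{1/(1+gamma)}``, iterated with renormalisation to
the budget; the landscape is multi-modal for gamma < 1, so several random
restarts are used and the best final dissipation kept.

Scanning ``alpha`` sweeps the optimised networks through a transition from
primal communities (each source supplies its own region; small lambda_2) to
dual communities (one strong vein links the sources; small lambda_2*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import PlaneGraph, GraphError, DisconnectedError, build_incidence, \
    laplacian, laplacian_pinv
from .dual import dual_laplacian, EmbeddingError
from .communities import fiedler
from .synth import TriangularResult

__all__ = [
    "SourceModel",
    "OptimizeResult",
    "sigma_D2",
    "injection_covariance",
    "sample_injections",
    "mean_square_flows",
    "dissipation",
    "optimize_network",
    "prune_network",
    "graph_fiedler_values",
    "transition_scan",
]


@dataclass(frozen=True)
class SourceModel:
    """Gaussian sinks + Dirichlet-fluctuating sources.

    Parameters (defaults follow the triangular-lattice experiments):
    ``mu, sigma`` Gaussian sink outflow mean/std (flow units; mu < 0 means
    sinks withdraw), ``K`` the scale of the source fluctuations and
    ``alpha`` the symmetric Dirichlet concentration.
    """

    n_sources: int = 2
    mu: float = -1.0
    sigma: float = 0.1
    K: float = 500.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.n_sources < 2:
            raise GraphError("need at least 2 sources")
        if self.alpha <= 0:
            raise GraphError("Dirichlet concentration must be positive")

    @property
    def sigma_D2(self) -> float:
        return sigma_D2(self.K, self.n_sources, self.alpha)


def sigma_D2(K: float, n_sources: int, alpha: float) -> float:
    """Variance of the scaled Dirichlet source fluctuation,
    ``K^2 (N_s-1) / (N_s^2 (N_s alpha + 1))``."""
    return K**2 * (n_sources - 1) / (n_sources**2 * (n_sources * alpha + 1))


def _role_indices(graph: PlaneGraph, sources) -> tuple[np.ndarray, np.ndarray]:
    src = np.array(sorted(graph.node_index(s) for s in sources), dtype=np.int64)
    mask = np.ones(graph.n_nodes, dtype=bool)
    mask[src] = False
    return src, np.flatnonzero(mask)


def injection_covariance(model: SourceModel, graph: PlaneGraph,
                         sources) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form mean and covariance of the joint injection vector.

    Sinks are i.i.d. ``N(mu, sigma^2)``; sources share the balancing term
    ``-(1/N_s) sum sinks`` (inducing sink-source and source-source
    covariance) plus the independent Dirichlet fluctuation with
    ``Var = sigma_D^2`` and pairwise covariance
    ``-K^2 / (N_s^2 (N_s alpha + 1))``.  Every sample is balanced exactly,
    so the covariance is supported on the zero-sum subspace.
    """
    ns = model.n_sources
    src, snk = _role_indices(graph, sources)
    if len(src) != ns:
        raise GraphError(f"expected {ns} sources, got {len(src)}")
    n = graph.n_nodes
    n_sinks = n - ns

    mean = np.empty(n)
    mean[snk] = model.mu
    mean[src] = -n_sinks * model.mu / ns

    var_x = (ns - 1) / (ns**2 * (ns * model.alpha + 1))
    cov_x = -1.0 / (ns**2 * (ns * model.alpha + 1))

    cov = np.zeros((n, n))
    cov[snk, snk] = model.sigma**2
    for a in src:
        cov[a, snk] = -model.sigma**2 / ns
        cov[snk, a] = -model.sigma**2 / ns
    base = n_sinks * model.sigma**2 / ns**2
    for a in src:
        for b in src:
            cov[a, b] = base + model.K**2 * (var_x if a == b else cov_x)
    return mean, cov


def sample_injections(model: SourceModel, graph: PlaneGraph, sources,
                      rng: np.random.Generator, size: int) -> np.ndarray:
    """Monte-Carlo samples of the joint injection vector, shape (size, N).

    Every row sums to zero exactly by construction.
    """
    ns = model.n_sources
    src, snk = _role_indices(graph, sources)
    P = np.empty((size, graph.n_nodes))
    sinks = rng.normal(model.mu, model.sigma, size=(size, len(snk)))
    X = rng.dirichlet(np.full(ns, model.alpha), size=size)
    P[:, snk] = sinks
    total = sinks.sum(axis=1)
    for j, a in enumerate(src):
        P[:, a] = -total / ns + model.K * (1.0 / ns - X[:, j])
    return P


def mean_square_flows(graph: PlaneGraph, mean: np.ndarray,
                      cov: np.ndarray) -> np.ndarray:
    """Per-edge ``<F_l^2>`` for Gaussian-ish injections with the given first
    two moments, propagated through the linear flow map ``F = W I L^+ P``."""
    I = build_incidence(graph)
    T = (graph.weights[:, None] * I) @ laplacian_pinv(graph)
    mF = T @ mean
    A = T @ cov
    var = np.einsum("ij,ij->i", A, T)
    return mF**2 + np.maximum(var, 0.0)


def dissipation(graph: PlaneGraph, msf: np.ndarray) -> float:
    """Expected dissipated energy ``sum_l <F_l^2>/w_l``."""
    return float(np.sum(msf / graph.weights))


@dataclass
class OptimizeResult:
    """Outcome of one (multi-restart) weight optimisation."""

    weights: np.ndarray
    dissipation: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)   # D per iteration (best run)
    gamma: float = 0.9


def _normalize(w: np.ndarray, gamma: float, budget: float) -> np.ndarray:
    return w * (budget / np.sum(w**gamma)) ** (1.0 / gamma)


def optimize_network(graph: PlaneGraph, mean: np.ndarray, cov: np.ndarray,
                     gamma: float = 0.9, budget: float = 1.0,
                     n_restarts: int = 1, seed: int | None = 0,
                     w0: np.ndarray | None = None,
                     tol: float = 1e-10, max_iter: int = 2000) -> OptimizeResult:
    """Minimise expected dissipation under ``sum w^gamma <= budget``.

    Fixed-point iteration of ``w ~ <F^2>^{1/(1+gamma)}`` with renormalisation
    to the budget; ``<F^2>`` is recomputed from the current weights at every
    step, so the dissipation decreases monotonically.  Weights of unused
    edges flow to (a numerical floor above) zero; prune them afterwards with
    :func:`prune_network`.
    """
    if not 0 < gamma <= 1:
        raise GraphError("gamma must be in (0, 1]")
    rng = np.random.default_rng(seed)
    best: OptimizeResult | None = None
    for r in range(max(1, n_restarts)):
        if w0 is not None and r == 0:
            w = np.asarray(w0, dtype=float)
        else:
            w = rng.uniform(0.5, 1.5, size=graph.n_edges)
        w = _normalize(w, gamma, budget)
        history = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            g = graph.with_weights(w)
            msf = mean_square_flows(g, mean, cov)
            D = dissipation(g, msf)
            history.append(D)
            w_new = msf ** (1.0 / (1.0 + gamma))
            w_new = np.maximum(w_new, 1e-12 * w_new.max())
            w_new = _normalize(w_new, gamma, budget)
            # stop on the weights, not on D: the dissipation flattens long
            # before the weak edges reach their stationary values
            if np.abs(w_new - w).max() <= tol * w.max():
                converged = True
                w = w_new
                break
            w = w_new
        res = OptimizeResult(weights=w, dissipation=history[-1], n_iter=it,
                             converged=converged, history=history, gamma=gamma)
        if best is None or res.dissipation < best.dissipation:
            best = res
    return best


def prune_network(graph: PlaneGraph, weights: np.ndarray, sources,
                  floor: float = 1e-8) -> PlaneGraph:
    """Drop edges below ``floor * max(weight)``; the surviving structure is
    the optimal network topology.

    Raises
    ------
    DisconnectedError
        If some sink ends up in a component without any source.
    """
    keep = np.flatnonzero(weights >= floor * weights.max())
    sub = graph.with_weights(weights).edge_subgraph(keep,
                                                    extra_nodes=graph.nodes)
    src = set(sources)
    for comp in sub.connected_components():
        if not comp & src and len(comp) > 0:
            raise DisconnectedError(
                "pruning disconnected sinks from every source")
    return sub


def graph_fiedler_values(graph: PlaneGraph,
                         weight_scale: float = 1.0) -> tuple[float, float]:
    """(lambda_2, lambda_2*) of a possibly pruned plane graph.

    ``weight_scale`` expresses the weights in units of a reference weight
    before the spectra are taken (``lambda_2`` divides by it, ``lambda_2*``
    multiplies): optimised networks concentrate almost the whole resource
    budget in a few backbone edges, so the scale-free quantity — weights per
    typical surviving edge — is what exposes the community structure rather
    than the budget allocation.

    A disconnected graph has ``lambda_2 = 0``.  ``lambda_2*`` is computed on
    the dual of each connected component with at least two interior faces
    and the minimum is reported; with no such component (a forest: no
    meaningful dual) it is ``inf``.
    """
    try:
        lam2 = fiedler(laplacian(graph))[0] / weight_scale
    except DisconnectedError:
        lam2 = 0.0
    lam2_star = math.inf
    comps = graph.connected_components()
    for comp in comps:
        sub = graph.induced_subgraph(comp) if len(comps) > 1 else graph
        if sub.n_edges - sub.n_nodes + 1 < 2:
            continue
        try:
            ls = fiedler(dual_laplacian(sub))[0] * weight_scale
        except (DisconnectedError, EmbeddingError):
            continue
        lam2_star = min(lam2_star, ls)
    return lam2, lam2_star


def transition_scan(lattice: TriangularResult, alphas,
                    model: SourceModel | None = None,
                    gamma: float = 0.9, n_restarts: int = 5,
                    seed: int = 0, prune_floor: float = 1e-8,
                    max_iter: int = 400) -> pd.DataFrame:
    """Optimise the lattice for each Dirichlet concentration ``alpha`` and
    record the primal/dual Fiedler values of the optimal networks.

    Returns one row per alpha with ``sigma_D2`` and the median and 25/75%
    quantiles of lambda_2 and lambda_2* over the restarts (every restart is
    analysed, not just the best, mirroring ensemble error bands).
    """
    base = model or SourceModel()
    graph, sources = lattice.graph, lattice.sources
    rows = []
    for i, alpha in enumerate(alphas):
        m = SourceModel(base.n_sources, base.mu, base.sigma, base.K,
                        float(alpha))
        mean, cov = injection_covariance(m, graph, sources)
        lam2s, lamds, Ds = [], [], []
        for r in range(n_restarts):
            res = optimize_network(graph, mean, cov, gamma=gamma,
                                   n_restarts=1, seed=seed + 1000 * i + r,
                                   max_iter=max_iter)
            try:
                pruned = prune_network(graph, res.weights, sources,
                                       floor=prune_floor)
            except DisconnectedError:
                continue
            scale = float(np.median(pruned.weights))
            l2, l2s = graph_fiedler_values(pruned, weight_scale=scale)
            lam2s.append(l2)
            lamds.append(l2s)
            Ds.append(res.dissipation)
        q = lambda x, p: float(np.percentile(x, p)) if x else math.nan
        rows.append({
            "alpha": float(alpha), "sigma_D2": m.sigma_D2,
            "lambda2_median": q(lam2s, 50), "lambda2_q25": q(lam2s, 25),
            "lambda2_q75": q(lam2s, 75),
            "lambda2_star_median": q(lamds, 50),
            "lambda2_star_q25": q(lamds, 25), "lambda2_star_q75": q(lamds, 75),
            "dissipation_median": q(Ds, 50), "n_runs": len(lam2s),
        })
    return pd.DataFrame(rows).sort_values("sigma_D2").reset_index(drop=True)
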