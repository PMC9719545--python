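"""Second-order phase oscillators: locked states and localized response.

Each node carries a phase ``theta_i`` evolving as::

    M_i d2theta/dt2 + D_i dtheta/dt = omega_i + sum_j w_ij sin(theta_j - theta_i)

with inertia ``M_i``, damping ``D_i`` and natural frequencies summing to zero
in the co-rotating frame.  Steady (phase-locked) states solve the static
balance equations; they are found by a damped Newton iteration whose
Jacobian is minus the weighted Laplacian with effective weights
``w_ij cos(theta_j - theta_i)``.

A localized perturbation (a permanent frequency shift ``domega`` at one
node, re-centred so frequencies still sum to zero) moves the locked state by
``dtheta_i``; a global phase shift is physically irrelevant, so responses are
reported in the mean-zero gauge.  The per-community variance of
``|dtheta_i|`` quantifies how strongly a community boundary attenuates the
response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph import PlaneGraph, GraphError, laplacian_pinv

__all__ = [
    "OscillatorSystem",
    "ResponseResult",
    "NoConvergenceError",
    "steady_state",
    "perturb_response",
    "community_response_variance",
    "integrate_transient",
]


class NoConvergenceError(GraphError):
    """Newton iteration found no phase-locked state."""


@dataclass(frozen=True)
class OscillatorSystem:
    """Oscillator network on a weighted graph.

    ``omega`` must sum to zero (use :meth:`centered` to enforce it);
    inertia and damping only matter for the transient integrator, the
    locked state is independent of them.
    """

    graph: PlaneGraph
    omega: np.ndarray
    inertia: float | np.ndarray = 1.0
    damping: float | np.ndarray = 1.0

    def centered(self) -> "OscillatorSystem":
        om = np.asarray(self.omega, dtype=float)
        return replace(self, omega=om - om.mean())

    def validate(self) -> None:
        om = np.asarray(self.omega)
        if om.shape != (self.graph.n_nodes,):
            raise GraphError("omega has wrong length")
        if abs(om.sum()) > 1e-9 * max(1.0, np.abs(om).max()):
            raise GraphError("natural frequencies must sum to zero")


def _residual(graph: PlaneGraph, omega: np.ndarray,
              theta: np.ndarray) -> np.ndarray:
    iu, iv = graph.edges[:, 0], graph.edges[:, 1]
    s = graph.weights * np.sin(theta[iv] - theta[iu])
    r = omega.copy()
    np.add.at(r, iu, s)
    np.subtract.at(r, iv, s)
    return r


def _effective_laplacian(graph: PlaneGraph, theta: np.ndarray) -> np.ndarray:
    iu, iv = graph.edges[:, 0], graph.edges[:, 1]
    w_eff = graph.weights * np.cos(theta[iv] - theta[iu])
    n = graph.n_nodes
    L = np.zeros((n, n))
    for k in range(graph.n_edges):
        a, b, w = iu[k], iv[k], w_eff[k]
        L[a, a] += w
        L[b, b] += w
        L[a, b] -= w
        L[b, a] -= w
    return L


def steady_state(system: OscillatorSystem,
                 theta0: np.ndarray | None = None,
                 tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Phase-locked state by damped Newton iteration, mean-zero gauge.

    Starts from ``theta = 0`` (or a supplied guess); if that fails, retries
    once from the linearized (DC) solution ``L^+ omega``.  The residual of
    the returned state is below ``tol``.
    """
    system.validate()
    graph = system.graph
    omega = np.asarray(system.omega, dtype=float)
    n = graph.n_nodes

    def newton(theta):
        theta = theta - theta.mean()
        r = _residual(graph, omega, theta)
        for _ in range(max_iter):
            rn = np.linalg.norm(r, np.inf)
            if rn < tol:
                return theta
            L = _effective_laplacian(graph, theta)
            J = np.full((n, n), 1.0 / n)
            try:
                step = np.linalg.solve(L + J, r)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(L, r, rcond=None)[0]
            step -= step.mean()
            alpha = 1.0
            while alpha > 1e-6:
                cand = theta + alpha * step
                cand -= cand.mean()
                rc = _residual(graph, omega, cand)
                if np.linalg.norm(rc, np.inf) < rn:
                    theta, r = cand, rc
                    break
                alpha *= 0.5
            else:
                return None
        return None

    start = np.zeros(n) if theta0 is None else np.asarray(theta0, dtype=float)
    theta = newton(start)
    if theta is None and theta0 is None:
        theta = newton(laplacian_pinv(graph) @ omega)   # DC fallback
    if theta is None:
        raise NoConvergenceError("no phase-locked state found")
    return theta - theta.mean()


@dataclass(frozen=True)
class ResponseResult:
    """Gauge-fixed steady-state phase shifts after a localized perturbation."""

    system: OscillatorSystem
    node: object
    domega: float
    baseline: np.ndarray
    perturbed: np.ndarray

    @property
    def delta_theta(self) -> np.ndarray:
        d = self.perturbed - self.baseline
        return d - d.mean()


def perturb_response(system: OscillatorSystem, node, domega: float,
                     baseline: np.ndarray | None = None) -> ResponseResult:
    """Response to a permanent frequency shift ``domega`` at ``node``.

    The shift is re-centred (every other node absorbs ``-domega/N``) so the
    perturbed frequencies still sum to zero; the new locked state is found
    starting from the baseline.
    """
    system = system.centered()
    if baseline is None:
        baseline = steady_state(system)
    n = system.graph.n_nodes
    bump = np.full(n, -domega / n)
    bump[system.graph.node_index(node)] += domega
    perturbed_sys = replace(system, omega=np.asarray(system.omega) + bump)
    perturbed = steady_state(perturbed_sys, theta0=baseline)
    return ResponseResult(system, node, domega, baseline, perturbed)


def community_response_variance(result: ResponseResult | np.ndarray,
                                community_indices,
                                literal: bool = False) -> float:
    """Variance of ``|dtheta_i|`` within a community.

    With ``literal=True`` returns the unnormalised expression
    ``sum |dtheta|^2 - (sum |dtheta|)^2`` (no 1/|C| factors); the default is
    the standard population variance.
    """
    d = result.delta_theta if isinstance(result, ResponseResult) else result
    x = np.abs(np.asarray(d)[list(community_indices)])
    if x.size == 0:
        raise GraphError("community is empty")
    if literal:
        return float((x**2).sum() - x.sum()**2)
    return float(x.var())


def perturb_response_dipole(system: OscillatorSystem, node_plus, node_minus,
                            domega: float,
                            baseline: np.ndarray | None = None
                            ) -> ResponseResult:
    """Response to a balanced dipole perturbation: ``+domega`` at one node,
    ``-domega`` at a second node.

    This is the oscillator analogue of an edge-failure dipole in a linear
    flow network: it injects no net frequency, so no flux is forced across a
    community boundary and the attenuation of the boundary itself is probed.
    """
    system = system.centered()
    if baseline is None:
        baseline = steady_state(system)
    bump = np.zeros(system.graph.n_nodes)
    bump[system.graph.node_index(node_plus)] += domega
    bump[system.graph.node_index(node_minus)] -= domega
    perturbed_sys = replace(system, omega=np.asarray(system.omega) + bump)
    perturbed = steady_state(perturbed_sys, theta0=baseline)
    return ResponseResult(system, (node_plus, node_minus), domega,
                          baseline, perturbed)


#: boundary-contrast ladders for the honeycomb response experiment; the
#: primal rungs stay above the loss-of-synchrony region and below the
#: weak-contrast regime where the static response is not yet attenuating.
PRIMAL_CONTRASTS = (1.0, 0.1, 0.05, 0.02, 0.01)
DUAL_CONTRASTS = (1.0, 10.0, 30.0, 100.0, 300.0)


def honeycomb_response_ladder(mode: str, contrasts=None, m: int = 4,
                              n: int = 6, reps: int = 50, seed: int = 0,
                              domega: float = 0.05,
                              omega_amp: float = 0.01):
    """Median non-perturbed-community response variance per boundary weight.

    ``mode`` is ``cut_set`` (weak crossing edges, primal communities) or
    ``cut_path`` (strong zig-zag vein, dual communities).  For each boundary
    weight, ``reps`` random natural-frequency draws (uniform, recentred) are
    locked, a dipole perturbation is applied across an edge of the perturbed
    (left) community near the boundary, and the variance of ``|dtheta|``
    over the *right* community is recorded; the rare draws without a locked
    state are skipped and counted.

    Returns a DataFrame with columns w, var_other_median (and quartiles),
    var_perturbed_median, n_failed.
    """
    import pandas as pd

    from .synth import honeycomb_lattice

    if contrasts is None:
        contrasts = PRIMAL_CONTRASTS if mode == "cut_set" else DUAL_CONTRASTS
    rows = []
    for w in contrasts:
        lat = honeycomb_lattice(m, n, mode, float(w))
        g = lat.graph
        left = sorted(lat.left_nodes)
        li = [g.node_index(nd) for nd in left]
        ri = [g.node_index(nd) for nd in sorted(lat.right_nodes)]
        mid_y = g.coords[:, 1].mean()
        node = min(left, key=lambda nd: abs(g.coords[g.node_index(nd), 0]
                                            - lat.split_x)
                   + abs(g.coords[g.node_index(nd), 1] - mid_y))
        nbrs = [g.nodes[j] for j, _ in g.adjacency()[g.node_index(node)]]
        partner = min(n2 for n2 in nbrs if n2 in lat.left_nodes)
        rng = np.random.default_rng(seed)
        vo, vp, failed = [], [], 0
        for _ in range(reps):
            om = rng.uniform(-omega_amp, omega_amp, g.n_nodes)
            system = OscillatorSystem(g, om).centered()
            try:
                resp = perturb_response_dipole(system, node, partner, domega)
            except NoConvergenceError:
                failed += 1
                continue
            vo.append(community_response_variance(resp, ri))
            vp.append(community_response_variance(resp, li))
        q25, med, q75 = np.percentile(vo, [25, 50, 75])
        rows.append({"w": float(w), "var_other_median": med,
                     "var_other_q25": q25, "var_other_q75": q75,
                     "var_perturbed_median": float(np.median(vp)),
                     "n_failed": failed})
    return pd.DataFrame(rows)


def integrate_transient(system: OscillatorSystem, theta0: np.ndarray,
                        t_span: tuple[float, float], n_eval: int = 200):
    """Integrate the full second-order dynamics (for illustration).

    Returns (t, theta(t)) with theta starting at rest from ``theta0``.
    """
    from scipy.integrate import solve_ivp

    system = system.centered()
    graph = system.graph
    n = graph.n_nodes
    M = np.broadcast_to(np.asarray(system.inertia, dtype=float), (n,))
    D = np.broadcast_to(np.asarray(system.damping, dtype=float), (n,))
    omega = np.asarray(system.omega, dtype=float)

    def rhs(t, y):
        theta, vel = y[:n], y[n:]
        acc = (omega + _residual(graph, np.zeros(n), theta) - D * vel) / M
        return np.concatenate([vel, acc])

    t_eval = np.linspace(*t_span, n_eval)
    sol = solve_ivp(rhs, t_span, np.concatenate([theta0, np.zeros(n)]),
                    t_eval=t_eval, rtol=1e-8, atol=1e-10)
    return sol.t, sol.y[:n]
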