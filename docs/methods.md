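# Methods

This note records the models implemented in `dualcomm`, the numerical and
design choices behind them, what the synthetic generators do and do not
emulate, and the package's known limitations.

## Plane graphs and duality

A `PlaneGraph` is a connected simple graph with strictly positive edge
weights, 2D node coordinates, and a fixed edge orientation (low node index →
high node index) that every downstream sign convention inherits. Planarity
of the straight-line drawing is checked on demand (O(M²) segment test); the
lattice generators construct non-crossing drawings by design.

Faces are enumerated from the rotation system induced by the coordinates
(counter-clockwise angular order of incident edges at each node). The
half-edge traversal rule "leave along the clockwise-next edge after the
arrival edge" produces interior faces counter-clockwise and the outer face
clockwise; the outer face is recognised as the unique face of most negative
signed area and excluded. A face count different from `M − N + 1` raises an
embedding error.

Two related dual objects are kept deliberately distinct:

* the **cycle-space matrix** `C` (full face boundaries, `IᵀC = 0` exactly),
  used by Kirchhoff's voltage law and the dual sensitivity formula, where
  `CᵀW⁻¹C` is positive definite because outer-boundary edges contribute to
  the diagonal;
* the **reduced dual graph**: interior faces as nodes, one edge per adjacent
  face pair with weight `w* = Σ 1/w` over the shared primal edges (parallel
  dual edges lumped). Its Laplacian — `CᵀW⁻¹C` restricted to edges shared by
  two interior faces — is what spectral community detection uses. Community
  detection on the unrestricted matrix would tie every peripheral face to an
  implicit outer node and destroy the cut-path bound.

For non-planar graphs an algebraic dual is built from a cycle basis
(minimum cycle basis by default, unit edge lengths, deterministic tie-break
by sorted node lists). Unordered basis cycles must be chordless, because a
node list with chords does not identify an edge set; ordered cycles of any
shape are accepted. Different bases give different duals; the face basis of
a plane graph reproduces the plane dual exactly.

## Spectral bisection, bounds, hierarchy

The Fiedler pair is computed densely (LAPACK `eigh`, subset) below 500
nodes and by a deflated shift-free Lanczos iteration with a deterministic
start vector above. The eigenvector sign is fixed (first entry of magnitude
> 1e−12 positive) so bisections are reproducible. Nodes with
`v₂ − h ≥ 0` form community 1 (`h = 0` by default; exact ties go to
community 1).

Cut-set and cut-path bounds are computed exactly as stated in the README.
`cut_path` additionally records whether the shared-edge set forms a single
simple path (a warning flag, not an error — on coarse lattices it can
branch) and verifies that removing the path's nodes disconnects the primal
graph.

Hierarchical decomposition bisects each subgraph on its own Laplacian
(primal side) or on the dual of its own embedding (dual side), to depth `m`.
Primal children are the two community-induced subgraphs (the cut-set is
thereby removed). Dual children are the *closures* of the two face
communities: every edge bounding a face of the community, including the
cut-path. The cut-path (a vein) is the shared boundary of the two blocks and
belongs to both children, exactly as its terminal nodes do; inside a child
it lies on the outer boundary, borders no pair of the child's faces, and so
cannot be selected again. The alternative — deleting the cut-path edges —
leaves the nodes beyond the vein dangling on no interior face, so they would
silently vanish from deeper levels and the leaves would no longer cover the
root node set. Branches stop (with a recorded reason) below 4 nodes, on
internal disconnection, or when a dual has fewer than two faces; isolated
nodes become singleton leaves.

## Linear flow networks and sensitivity

Potentials solve `Lθ = P` in the mean-zero gauge: densely via the rank-one
deflation `(L + 𝟙𝟙ᵀ/N)⁻¹` up to ~2000 nodes, above that by conjugate
gradients on the deflated operator (tolerance 1e−12). The additive constant
of `θ` is physically irrelevant; all outputs are gauge-fixed.

The sensitivity factor of trigger edge `e` is computed in both the primal
(node-potential) and dual (cycle-flow) formulation; their exact agreement —
verified to 1e−8 over random weighted lattices — is the package's core
cross-check, since the two routes share no linear algebra beyond the edge
list. Bridges are handled explicitly: an edge on no cycle has a zero
cycle-space column, so the dual form returns zero off-diagonal sensitivity,
which matches the primal computation.

Line outages use the rerouting identity `ΔF_ℓ = η_{e,ℓ} F_e/(1 − η_{e,e})`,
validated against deleting the edge and re-solving; `η_{e,e} → 1` (a
bridge) raises an error.

The mean flow ratio `R` averages `R(e,d)` — mean `|η|` over other-community
edges at unweighted edge distance `d` divided by the same-community mean at
`d` — over all trigger edges and distances where both averages exist. Edge
distance is the minimum hop count between endpoints, kept unweighted so the
binning does not move while weights are scanned. An edge belongs to a
community only if both endpoints (primal) or all bordering interior faces
(dual) do; boundary edges are excluded from both numerator and denominator
and never serve as triggers.

## Threshold cascades

Synchronous updates of the weighted-average rule with uniform threshold
`φ = 0.18`; monotone dynamics reach the fixed point in at most `N` steps.
The default boundary experiment uses a 48×20 lattice whose candidate edge
set is every edge with both endpoints in the central 4 columns (4 columns of
vertical edges plus the 3 internal crossing layers); a random 80% of the
candidates are reweighted to `w` per replicate, and 5% of the nodes left of
the strip are seeded.

Why this geometry: the two blocking mechanisms are different. A weak strip
blocks because infection arriving over a weak edge contributes only
`~w/(w+3)` ≈ 0.0033 ≪ φ to the weighted average of a node whose other edges
are normal (leakage); a strong strip blocks because a strip node's
denominator is inflated by its strong edges, `1/(2+2·10²)` ≈ 0.005 ≪ φ
(dilution). With 20% of candidate edges left at weight 1, single unweighted
"holes" must not breach the boundary: a multi-layer strip makes a breach
require several aligned holes, and a hole itself protects its endpoint in
the weak regime by inflating the denominator. φ = 0.18 sits below the 1/4
single-neighbour flip point of an interior degree-4 node (so the
homogeneous lattice cascades globally from sparse seeds) and above both
blocking scales. The lattice is wider than it is tall because the strong
strip stays healthy (the blocked front stops just left of it) while the weak
strip's interior partially fills: both medians sit near one half of the
nodes only when the ~2-column asymmetry is small against the lattice width;
at 48 columns the blocked medians are ≈ 0.503 and ≈ 0.458.

The generator emulates the blocked/global dichotomy, not any particular
real substrate: thresholds are uniform, the lattice is regular, and seeds
are spatially random. Passing tests show the mechanism, not robustness to
threshold heterogeneity or irregular geometry.

## Optimal supply networks

Sinks draw i.i.d. `N(μ, σ²)` (defaults μ = −1, σ = 0.1); the `N_s = 2`
sources balance the total and share it by a symmetric Dirichlet vector
scaled by `K = 500`, giving the closed-form joint injection moments
implemented in `injection_covariance` (every sample is balanced exactly, so
the covariance lives on the zero-sum subspace). The analytic moments are
cross-checked against Monte-Carlo sampling of the constructive definition.

Expected dissipation is minimised under `Σw^γ ≤ 1` (γ = 0.9) by the classic
fixed-point rescaling `w ∝ ⟨F²⟩^{1/(1+γ)}` with renormalisation each step.
Convergence is declared on the weights (max change ≤ 1e−10 of the largest
weight), not on the dissipation, which flattens long before the weak edges
reach stationarity; at convergence the Karush–Kuhn–Tucker ratio
`⟨F²⟩/w^{1+γ}` is constant across surviving edges to better than 1%. The
landscape is multi-modal for γ < 1, so scans use several uniform-random
restarts (all restarts are analysed, mirroring ensemble error bands; the
best-dissipation run is returned by `optimize_network`). Edges below
`1e−8 × max(w)` are pruned afterwards; pruning that strands a sink from all
sources is an error.

When reporting the transition, `λ₂` and `λ₂*` of the pruned optimum are
computed with weights measured in units of the **median surviving weight**.
The raw spectra carry the global allocation scale — in the vein phase almost
the whole budget sits in a few backbone edges, thinning every sink edge by a
common factor — and that scale, not structure, dominates the raw Fiedler
values. The scale-free normalisation exposes the crossover: on the default
54-node triangular strip, median `λ₂` rises ≈ 0.036 → 0.15 and `λ₂*` falls
≈ 6.2 → 0.02 as `σ_D²` grows from ~3 to ~6·10⁴, with the `(λ₂ < λ₂*)`
ordering flipping between the endpoints. Desk-scale note: the scan uses the
54-node lattice, 7 values of α in [10⁻², 10⁴], and 5 restarts.

## Oscillator networks

Locked states solve the static balance by damped Newton iteration (Jacobian
= minus the effective Laplacian with weights `w cos Δθ`; rank-one deflation;
backtracking line search; residual < 1e−10; DC-solution fallback start).
Failure to converge signals the absence of a stable locked state at those
parameters and is raised, not masked. A stability check (effective
Laplacian PSD, all edge phase differences < π/2) is asserted in tests.

Two perturbation protocols are provided. `perturb_response` applies a
permanent single-node frequency shift, recentred globally — the literal
"add δω at a node" reading. For the community-attenuation experiment the
package uses `perturb_response_dipole`: ±δω across an edge of the perturbed
community near the boundary, the oscillator analogue of the edge-failure
dipole used in the flow-network analysis. The reason is structural: a
recentred single-node shift forces a fixed net frequency flux
`δω·N_other/N` across the boundary, so the non-perturbed community's
response *saturates* (and for weak boundaries under a wide frequency spread
the locked state disappears altogether); a dipole injects no net frequency
and probes the boundary attenuation itself. Defaults for the ladder:
honeycomb 4×6 (68 nodes), ω i.i.d. uniform ±0.01 recentred, δω = 0.05,
50 draws, contrast ladders (1, 0.1, 0.05, 0.02, 0.01) for the weak-cut and
(1, 10, 30, 100, 300) for the strong-vein boundary. The weak-cut ladder
skips the range just below contrast 1 where the static response still rises
slightly before the attenuation regime sets in.

The per-community response variance is the standard population variance of
`|Δθ_i|`; the literal unnormalised expression `Σ|Δθ|² − (Σ|Δθ|)²`
(dimensionally inconsistent as a variance — it lacks the 1/|C| factors) is
also available via `literal=True`, flagged rather than silently corrected.

## Synthetic generators

All generators are pure functions of their arguments (bit-identical
reruns), return their engineered boundary explicitly, and pass plane-graph
validation. The vein-hierarchy lattice places its veins off-centre (quarter
lines) by default: vein positions in real venation networks are set by the
vasculature, whereas a primal spectral bisection prefers the balanced
geometric cut; centring the veins would make the two coincide by accident
and void the contrast between primal and dual decompositions. Honeycomb
cut-paths are found as a horizontal-deviation-penalised shortest path
between the bottom and top of the central band, yielding the natural
zig-zag vein.

## Numerical conventions and degenerate inputs

* Laplacian pseudo-solves: rank-one deflation, dense ≤ 2000 nodes, CG above;
  disconnected graphs fall back to a true pseudoinverse where meaningful
  (`λ₂` of a disconnected graph is reported as 0 by the transition scan;
  a forest's dual Fiedler value as ∞).
* Fiedler-vector ties (`v₂ = h`) go to community 1; all eigensolver starts
  are deterministic.
* Outer face: most negative signed area; degenerate duals (< 2 faces) raise.
* Weights must be strictly positive and finite everywhere; a cut of weight
  exactly 0 is modelled by removing edges, not by zero weights.

## Limitations

* Face enumeration and the planarity check are O(M log M)–O(M²) and meant
  for desk-scale graphs (≲ 10⁴ edges), matching the experiments here.
* The threshold-cascade and oscillator conclusions are demonstrated on
  regular lattices with the documented protocols; heterogeneous thresholds,
  degree disorder, and transient (finite-time) responses are out of scope.
* The dissipation optimiser implements the continuous-weight fixed point
  with pruning; it does not search over discrete topologies.
* Duals of non-planar graphs depend on the cycle basis; only the
  minimum-cycle-basis route is provided.
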