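"""Primal vs dual spectral communities and their connectivity bounds.

A square lattice is split into two primal communities by *weakening* the
crossing edges, or into two dual communities by *strengthening* the central
column (a vein).  In both cases the Fiedler value is bounded by the
topological connectivity of the boundary (cut-set weight, or cut-path
inverse weight), and the bound tightens as the contrast grows.
"""
import dualcomm as dc

print("primal communities (weak cut-set), lattice 10x8:")
for eps in (1e-1, 1e-2, 1e-3):
    lat = dc.square_lattice(10, 8, "cut_set", eps)
    bis = dc.bisect(lat.graph)
    print(f"  w_cut={eps:<6g} lambda2={bis.lam2:.3e}  mu2={bis.mu2:.3e}  "
          f"gap={(bis.mu2 - bis.lam2) / bis.mu2:.2%}")

print("dual communities (strong cut-path / vein):")
for c in (1e1, 1e2, 1e3):
    lat = dc.square_lattice(10, 8, "cut_path", c)
    bis = dc.bisect(dc.build_dual(lat.graph))
    print(f"  w_vein={c:<6g} lambda2*={bis.lam2:.3e} mu2*={bis.mu2:.3e} "
          f"gap={(bis.mu2 - bis.lam2) / bis.mu2:.2%}  "
          f"cut-path disconnects primal: {bis.boundary_disconnects}")

print("\nThe shrinking gap shows both bounds become exact as the")
print("corresponding (primal or dual) connectivity vanishes.")
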