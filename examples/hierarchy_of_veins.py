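"""Hierarchical decomposition of a vein-structured lattice.

A lattice with a strong primary vein (vertical) and a weaker secondary vein
(horizontal) mimics the nested organisation of a leaf venation network.
Repeated spectral bisection of the *dual* graph recovers the vein-bounded
blocks exactly; the same procedure on the primal graph splits along the
balanced geometric cut instead and misses the veins.
"""
from sklearn.metrics import adjusted_rand_score

import dualcomm as dc

vh = dc.vein_hierarchy_lattice(levels=2)
print(f"lattice: {vh.graph.n_nodes} nodes; primary vein weight 1e3, "
      "secondary 1e2 (off-centre at the quarter lines)")

tree = dc.hierarchical_decompose(vh.graph, 2, side="dual")
leaves = tree.leaf_node_sets()
exact = sorted(map(sorted, leaves)) == sorted(map(sorted, vh.truth))
print(f"dual decomposition: {len(leaves)} leaves; matches the vein blocks "
      f"exactly: {exact}")

tree_p = dc.hierarchical_decompose(vh.graph, 2, side="primal")
labels = {}
for i, leaf in enumerate(tree_p.leaf_node_sets()):
    for n in leaf:
        labels[n] = i
truth = vh.truth_labels()
nodes = sorted(truth)
ari = adjusted_rand_score([truth[n] for n in nodes],
                          [labels[n] for n in nodes])
print(f"primal decomposition: adjusted Rand vs vein blocks = {ari:.3f} "
      "(no alignment: primal splits ignore strong veins)")
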