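"""Build a plane graph, enumerate its faces and construct the weighted dual.

Two unit squares share one edge of weight 4; the dual therefore has two
face-nodes joined by a single edge of weight 1/4 — strong primal connections
are weak dual ones.
"""
import numpy as np

import dualcomm as dc

edges = [((0, 0), (1, 0)), ((1, 0), (1, 1)), ((1, 1), (0, 1)),
         ((0, 0), (0, 1)), ((1, 0), (2, 0)), ((2, 0), (2, 1)),
         ((2, 1), (1, 1))]
coords = {(i, j): (i, j) for i in range(3) for j in range(2)}
weights = {e: 1.0 for e in edges}
weights[((1, 0), (1, 1))] = 4.0          # the shared edge

graph = dc.PlaneGraph.from_edgelist(edges, coords, weights)
faces = dc.enumerate_faces(graph)
dual = dc.build_dual(graph, faces)

print(f"primal: {graph.n_nodes} nodes, {graph.n_edges} edges")
print(f"interior faces: {faces.n_faces} (= M - N + 1 = "
      f"{graph.n_edges - graph.n_nodes + 1})")
print(f"dual edge weight w* = {dual.weights[0]}  (inverse of the shared "
      "primal weight 4)")
print("dual Laplacian L* =")
print(dc.dual_laplacian(graph, faces))

# the cycle-edge incidence matrix spans the cycle space: I^T C = 0
I = dc.build_incidence(graph)
C = dc.cycle_incidence(faces)
print("max |I^T C| =", np.abs(I.T @ C).max(), " (exactly zero: columns are "
      "source-free cycle flows)")
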