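import numpy as np
import pytest

import dualcomm as dc


@pytest.fixture
def unit_square():
    """Single square cycle: 4 nodes, 4 edges, one interior face."""
    return dc.PlaneGraph.from_edgelist(
        [(0, 1), (1, 2), (2, 3), (0, 3)],
        {0: (0, 0), 1: (1, 0), 2: (1, 1), 3: (0, 1)})


@pytest.fixture
def two_squares():
    """Two unit squares sharing the vertical edge (1,0)-(1,1) (weight 4)."""
    edges = [((0, 0), (1, 0)), ((1, 0), (1, 1)), ((1, 1), (0, 1)),
             ((0, 0), (0, 1)), ((1, 0), (2, 0)), ((2, 0), (2, 1)),
             ((2, 1), (1, 1))]
    coords = {(i, j): (i, j) for i in range(3) for j in range(2)}
    w = {e: 1.0 for e in edges}
    w[((1, 0), (1, 1))] = 4.0
    return dc.PlaneGraph.from_edgelist(edges, coords, w)


@pytest.fixture
def barbell():
    """Two unit triangles joined by a bridge of weight 1e-6."""
    edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    coords = {0: (0, 0), 1: (1, 0), 2: (0.5, 0.8), 3: (2, 0.8),
              4: (2.5, 0), 5: (3, 0.8)}
    return dc.PlaneGraph.from_edgelist(edges, coords, [1, 1, 1, 1, 1, 1, 1e-6])


def random_weighted_lattice(nx_, ny_, seed):
    lat = dc.square_lattice(nx_, ny_)
    rng = np.random.default_rng(seed)
    return lat.graph.with_weights(rng.uniform(0.3, 3.0, lat.graph.n_edges))


@pytest.fixture
def weighted_6x6():
    return random_weighted_lattice(6, 6, 0)
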