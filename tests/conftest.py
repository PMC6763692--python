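import numpy as np
import pytest

import cablenet as cn


def make_ring(n_types=2, cells_per_type=2, n_dend=2, nseg_per_dend=2,
              seed=1, **kw):
    """Small ring network model used across test modules."""
    return cn.ring_model(n_types=n_types, cells_per_type=cells_per_type,
                         n_dend=n_dend, nseg_per_dend=nseg_per_dend,
                         seed=seed, **kw)


def random_parent(rng, n):
    """Random ordered tree: parent[i] uniform in [0, i)."""
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        parent[i] = rng.integers(0, i)
    return parent


def dense_tree_solve(d, b, rhs, parent):
    """Independent oracle: assemble the symmetric tree matrix densely."""
    n = len(d)
    M = np.diag(np.asarray(d, dtype=float))
    for i in range(1, n):
        p = parent[i]
        if p < 0:
            continue
        M[i, p] = b[i]
        M[p, i] = b[i]
    return np.linalg.solve(M, rhs)


@pytest.fixture
def ring_model_small():
    return make_ring()


@pytest.fixture
def hh_soma_state():
    model = cn.single_compartment(mechs=[("hh", {})])
    return cn.SimState(model)
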