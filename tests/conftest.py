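import numpy as np
import pytest

from fluxdir import models, simulate


@pytest.fixture(scope="session")
def basal_model():
    """Single constitutive node: birth 30, death x (stationary Poisson(30))."""
    return models.build_michaelis_menten(np.zeros((1, 1), dtype=int))


@pytest.fixture(scope="session")
def chain_model():
    """Two-node chain 0 -> 1: constitutive parent (Poisson(30)),
    Michaelis-Menten child with lam = k = 100, both lifetimes 1."""
    G = np.array([[0, 0], [1, 0]])
    return models.build_michaelis_menten(G)


@pytest.fixture(scope="session")
def chain_exact(chain_model):
    """Exact stationary law of the chain on a generous truncation."""
    return simulate.solve_stationary(chain_model, caps=[90, 70])


@pytest.fixture(scope="session")
def chain_snapshots(chain_model):
    return simulate.sample_snapshots(chain_model, 10000, seed=12345)


def poisson_snapshots(means, N, seed):
    """Independent Poisson columns wrapped as a snapshot matrix (no SSA)."""
    rng = np.random.default_rng(seed)
    data = np.column_stack([rng.poisson(m, size=N) for m in means])
    labels = [f"x{i}" for i in range(len(means))]
    return simulate.SnapshotMatrix(data, labels)
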