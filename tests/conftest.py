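import numpy as np
import pytest

import slgca


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_slice():
    """A small 3-domain slice with clear domain signal, shared across tests."""
    return slgca.simulate_slice(
        slgca.SimConfig(n_spots_side=10, n_domains=3, n_genes=60, seed=1)
    )


@pytest.fixture(scope="session")
def toy_pair():
    """Two slices with a strong batch effect, for integration tests."""
    return slgca.simulate_multislice(
        slgca.SimConfig(n_spots_side=10, n_domains=3, n_genes=60, n_slices=2, batch_sigma=1.0, seed=2)
    )


@pytest.fixture
def random_dataset(rng):
    counts = rng.poisson(2.0, size=(50, 20)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0
    return slgca.ExpressionDataset(
        counts=counts,
        coords=rng.uniform(0, 100, size=(50, 2)),
        gene_names=[f"g{i}" for i in range(20)],
        spot_ids=[f"s{i}" for i in range(50)],
    )
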