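import numpy as np
import pytest

from betadismantle import CommunityMatrix, DistanceMatrix
from betadismantle.synthetic_data import fixture_config, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_dm(rng):
    """Factory for random valid distance matrices."""

    def make(n: int, labels=None) -> DistanceMatrix:
        a = rng.random((n, n))
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
        return DistanceMatrix(labels or [f"s{i}" for i in range(n)], a)

    return make


@pytest.fixture
def random_incidence(rng):
    """Factory for random incidence CommunityMatrix with no empty sites."""

    def make(n_sites: int, n_species: int, p: float = 0.5) -> CommunityMatrix:
        while True:
            x = (rng.random((n_sites, n_species)) < p).astype(float)
            if np.all(x.sum(axis=1) > 0):
                return CommunityMatrix(
                    [f"s{i}" for i in range(n_sites)],
                    [f"sp{j}" for j in range(n_species)],
                    x,
                )

    return make


@pytest.fixture(scope="session")
def fixture_dataset():
    """The packaged small synthetic dataset: 12 sites, 2 guilds x 20 species."""
    return generate_dataset(fixture_config(seed=0), seed=0)
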