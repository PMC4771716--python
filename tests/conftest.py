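import numpy as np
import pytest

from memscale import (
    Coordinates,
    SpatialWeights,
    SyntheticConfig,
    build_gabriel_graph,
    make_dataset,
    mem_basis,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3_weights():
    """Path graph on 3 sites: 1-2-3."""
    return SpatialWeights(n=3, edges=((0, 1), (1, 2)))


@pytest.fixture(scope="session")
def coords30():
    r = np.random.default_rng(777)
    return Coordinates(xy=r.uniform(0, 100, (30, 2)))


@pytest.fixture(scope="session")
def basis30(coords30):
    return mem_basis(build_gabriel_graph(coords30))


@pytest.fixture(scope="session")
def weights30(coords30):
    return build_gabriel_graph(coords30)


@pytest.fixture(scope="session")
def small_survey():
    """Compact synthetic survey for pipeline-level tests."""
    table, truth = make_dataset(SyntheticConfig(n_sites=120, seed=42))
    return table, truth
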