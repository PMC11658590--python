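import numpy as np
import pytest

from ecozone import GridLayer, GridSpec, SyntheticConfig, generate_study_area
from ecozone.synthetic import example_matrices


@pytest.fixture
def spec10() -> GridSpec:
    return GridSpec(10, 10, 30.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def random_layer(spec10, rng) -> GridLayer:
    return GridLayer(spec10, rng.uniform(0, 100, size=(10, 10)))


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study area shared by the slower integration tests."""
    return generate_study_area(SyntheticConfig(seed=7, n_rows=48, n_cols=48))


@pytest.fixture(scope="session")
def matrices():
    return example_matrices()
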