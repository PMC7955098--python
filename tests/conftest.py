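import warnings

import numpy as np
import pytest

from escape.simulate import LandscapeConfig, generate_landscape

warnings.filterwarnings("ignore", message=".*empty.*", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    """A reduced landscape for fast unit tests (same rates, smaller genome)."""
    return LandscapeConfig(
        genome={"chr1": 2_000_000},
        n_promoters=40,
        n_enhancers=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def default_truth():
    """The default study-condition landscape used by end-to-end checks."""
    return generate_landscape(LandscapeConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
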