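import numpy as np
import pytest

from trichrome import phantom


@pytest.fixture(scope="session")
def small_projection_phantom():
    """Small disjoint-population phantom reused by several suites."""
    return phantom.generate_projection_phantom(
        shape=(300, 300), n_per_population=(4, 4, 4), width_px=2, seed=11, block_px=30
    )


@pytest.fixture(scope="session")
def overlap_projection_phantom():
    return phantom.generate_projection_phantom(
        shape=(600, 600),
        n_per_population=(10, 10, 10),
        overlap_fraction=0.3,
        seed=7,
        block_px=30,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
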