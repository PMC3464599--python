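import numpy as np
import pytest

import mokkenpy as mp

#: study-condition defaults used across the suite: a medium-strength
#: 6-item binary scale under the double monotonicity model
DMM_LOCATIONS = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)
DMM_DISCRIMINATION = 1.5


@pytest.fixture(scope="session")
def guttman_matrix():
    """Deterministic 6-item error-free cumulative data, 10 per pattern."""
    return mp.generate_guttman([10] * 7)


@pytest.fixture(scope="session")
def dmm_config():
    return mp.SyntheticConfig(
        n=2000,
        items=mp.equal_discrimination_binary(DMM_LOCATIONS, DMM_DISCRIMINATION),
        seed=1234,
    )


@pytest.fixture(scope="session")
def dmm_matrix(dmm_config):
    return mp.generate(dmm_config)


def random_small_matrix(rng):
    """Random instance within the enumeration-oracle envelope."""
    k = rng.integers(2, 5)
    n = rng.integers(4, 13)
    m = rng.integers(1, 3)
    while True:
        values = rng.integers(0, m + 1, size=(n, k))
        if np.all(values.var(axis=0) > 0):
            return values
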