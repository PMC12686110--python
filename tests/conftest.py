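import numpy as np
import pytest

from mptrt import Condition, generate_dataset


@pytest.fixture(scope="session")
def null_dataset():
    """Zero-effect DIM dataset (all RT components identical), n=100/tree."""
    return generate_dataset(Condition("DIM", "delta_mu", 0, 100), seed=101)


@pytest.fixture(scope="session")
def effect_dataset():
    """DIM dataset with a strong location/scale manipulation, n=300/tree."""
    return generate_dataset(Condition("DIM", "delta_mu", 75, 300), seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
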