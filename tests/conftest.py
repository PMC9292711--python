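import numpy as np
import pytest

from sysdrift import oscillator, random_system


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def osc():
    return oscillator()


@pytest.fixture
def stable_pair():
    """Two stable random 3-gene systems for distance tests."""
    return (
        random_system(3, 1, 1, seed=5, spectral_bound=-0.3),
        random_system(3, 1, 1, seed=6, spectral_bound=-0.3),
    )
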