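import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gabor_population():
    """46 Gabor fixtures tiling [0, 180) — shared ground truth."""
    from plasticv1.synthetic import make_gabor_population

    return make_gabor_population(46, np.random.default_rng(99))
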