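import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_compositions(rng):
    """50 strictly positive 5-part compositions closed to 1440."""
    from mbtrans.compositions import close

    raw = rng.lognormal(mean=3.0, sigma=1.0, size=(50, 5))
    return close(raw)
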