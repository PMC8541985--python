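import numpy as np
import pytest

from stereoprf.grid import make_grid


@pytest.fixture(scope="session")
def small_grid():
    """2-deg field at 10 px/deg: 41x41, cheap enough for exact checks."""
    return make_grid(2.0, 10)


@pytest.fixture(scope="session")
def field_grid():
    """Full-size 10-deg field used by scan designs."""
    return make_grid(10.0, 10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
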