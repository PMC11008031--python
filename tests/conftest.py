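import numpy as np
import pytest
from hypothesis import settings

from httscan import _seq
from httscan.homology_search import local_search

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Pay the one-off JIT compilation cost before any timed work."""
    rng = np.random.default_rng(0)
    g = _seq.random_seq(rng, 2000, 0.5)
    local_search(g[500:700], g)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
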