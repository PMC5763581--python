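import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """64-px phantom image shared by the heavier fitting tests."""
    from respfit.phantom import make_phantom

    return make_phantom(64, seed=0)
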