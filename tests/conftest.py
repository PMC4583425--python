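import numpy as np
import pytest

from msfoot.multiscale import build_pyramid_stack
from msfoot.simulate import make_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def footprint_strong_small():
    """Small strong-footprint dataset shared across fast tests."""
    return make_fixture("footprint_strong", seed=7, N=400)


@pytest.fixture(scope="session")
def footprint_strong_stack(footprint_strong_small):
    return build_pyramid_stack(footprint_strong_small.counts)
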