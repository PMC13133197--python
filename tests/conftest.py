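import numpy as np
import pytest

from spinecage.phantom import PhantomSpec, make_vertebra_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small single-vertebra phantom shared across tests."""
    spec = PhantomSpec(body_half_axes=(10.0, 8.0, 7.0), seed=11)
    vol, truth = make_vertebra_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
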