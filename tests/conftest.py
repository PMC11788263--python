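import numpy as np
import pytest

from ribsep.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic 128x128 phantom shared by read-only tests."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_phantom(PhantomConfig(seed=2, noise_sd=0.01, n_corruptors=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
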