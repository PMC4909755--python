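import numpy as np
import pytest
from hypothesis import settings

import brainparc as bp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    """A reproducible 20-leaf simulated tree."""
    return bp.run_fragmentation(
        bp.ModelParams(mu=0.0, n_target=20, noise_sd=0.1, seed=42)
    )


@pytest.fixture
def lognormal_volumes():
    """90 lognormal volumes at the dispersion scale of real parcellations."""
    return bp.make_lognormal_volumes(90, sigma=1.24, seed=7)
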