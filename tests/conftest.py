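import numpy as np
import pytest
from hypothesis import settings

from octseg.phantom import PhantomSpec, generate_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_spec():
    """64×64 phantom family used throughout the unit tests."""
    return PhantomSpec(height=64, width=64, n_pockets=2,
                       pocket_scale_range=(4.0, 10.0), seed=0)


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
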