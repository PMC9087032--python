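import numpy as np
import pytest
from hypothesis import settings

from lumbarqc.phantom import PhantomSpec, generate_phantom

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ap_sample():
    """A qualified anteroposterior phantom at default resolution."""
    return generate_phantom(PhantomSpec(position="AP", seed=101))


@pytest.fixture(scope="session")
def lateral_sample():
    return generate_phantom(PhantomSpec(position="lateral", seed=102))


@pytest.fixture(scope="session")
def oblique_sample():
    return generate_phantom(PhantomSpec(position="oblique", seed=103))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
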