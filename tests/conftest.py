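import numpy as np
import pytest

from reconformer import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom48():
    """Structured brain-like phantom, 48^3 at 1 mm, fixed seed."""
    spec = PhantomSpec(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0), seed=11)
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
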