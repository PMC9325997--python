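import numpy as np
import pytest

from eigenfluor import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Default 5-tissue phantom at test scale, with its label map."""
    spec = PhantomSpec(height=96, width=160, seed=11)
    cube, labels = generate_phantom(spec)
    return cube, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
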