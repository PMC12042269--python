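import numpy as np
import pytest

from slmassembly import InteractionParams, make_targets


@pytest.fixture(scope="session")
def targets25():
    """The standard two 5x5 targets over 25 labelled particles."""
    return make_targets(25, 2)


@pytest.fixture(scope="session")
def params_default():
    return InteractionParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
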