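import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    from mrbcr.io import ImageStack

    return ImageStack(rng.uniform(0.0, 1.0, size=(3, 40, 40)).astype(np.float32))
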