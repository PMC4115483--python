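import numpy as np
import pytest

import tonguetrack as tt


@pytest.fixture(scope="session")
def phantom_a():
    """Noiseless /a/ phantom frame and its ground truth."""
    return tt.generate_midsagittal_frame(tt.ARCHETYPES["a"], seed=11)


@pytest.fixture(scope="session")
def phantom_i():
    return tt.generate_midsagittal_frame(tt.ARCHETYPES["i"], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
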