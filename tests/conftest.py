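import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20160729)


@pytest.fixture
def random_tensor(rng):
    """A modest random 3-D count tensor with some empty cells."""
    def make(shape=(3, 4, 2), total=200):
        t = rng.multinomial(total, np.ones(np.prod(shape)) / np.prod(shape))
        t = t.reshape(shape)
        t[rng.random(shape) < 0.15] = 0
        if t.sum() == 0:
            t[0, 0, 0] = 1
        return t
    return make
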