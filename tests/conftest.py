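import numpy as np
import pytest

from bilattice import BilayerState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bilayer(plus, minus, t=0):
    """Build a BilayerState from layer +1 and layer -1 grids."""
    return BilayerState(np.stack([np.asarray(minus, dtype=np.int8),
                                  np.asarray(plus, dtype=np.int8)]), t=t)


@pytest.fixture
def random_state(rng):
    """A 6x6 bilayer with i.i.d. half/half strategies."""
    return BilayerState((rng.random((2, 6, 6)) < 0.5).astype(np.int8))
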