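import numpy as np
import pytest

from visuohaptic.inventory import build_inventory


@pytest.fixture(scope="session")
def inv33():
    """Standard visual-exposure inventory: 3 horizontal + 3 vertical true pairs."""
    return build_inventory(3, 3, seed=11)


@pytest.fixture(scope="session")
def inv22():
    """Standard haptic-exposure inventory: 2 + 2 true pairs."""
    return build_inventory(2, 2, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
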