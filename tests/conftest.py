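import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def block_9x9():
    """7x7 foreground block on a 9x9 grid; center of mass at (4, 4)."""
    label = np.zeros((9, 9))
    label[1:8, 1:8] = 1.0
    return label


@pytest.fixture
def hole_fixture(block_9x9):
    """Soft prediction with a single false-negative pixel at (4, 5) that is
    enclosed by predicted foreground: an internal hole."""
    pred = np.where(block_9x9 > 0, 0.9, 0.1)
    pred[4, 5] = 0.1
    return pred, block_9x9


@pytest.fixture
def rim_fixture(block_9x9):
    """Soft prediction with the lesion's rightmost column erased: an edge
    false-negative strip whose outward rays never re-enter foreground."""
    pred = np.where(block_9x9 > 0, 0.9, 0.1)
    pred[1:8, 7] = 0.1
    return pred, block_9x9
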