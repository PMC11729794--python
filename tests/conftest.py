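import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_far_clusters():
    """Four 1-D points forming two tight, well-separated clusters."""
    return np.array([[0.0], [0.1], [10.0], [10.1]])
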