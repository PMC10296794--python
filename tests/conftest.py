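import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def separable_dataset():
    """Two well-separated Gaussian blobs in 2-D, one-hot targets."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(-1.0, 0.3, (50, 2)),
                   rng.normal(1.0, 0.3, (50, 2))])
    y = np.array([0] * 50 + [1] * 50)
    Y = np.eye(2)[y]
    return X, y, Y
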