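import numpy as np
import pytest

from herbscreen.chem import Fingerprint


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fp(rng, width=64, density=0.3) -> Fingerprint:
    return Fingerprint((rng.random(width) < density).astype(np.uint8))


@pytest.fixture
def separable_toy(rng):
    """Two well-separated Gaussian blobs in 2-D; 10 + 10 points."""
    X = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(4, 0.5, (10, 2))])
    y = np.concatenate([np.zeros(10), np.ones(10)])
    return X, y
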