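import numpy as np
import pytest

from epshar import default_spec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 20 windows of 32-sample 6-channel signals (fast)."""
    return generate(default_spec(n_classes=3, n_per_class=20, samples=32, seed=7))


@pytest.fixture(scope="session")
def headline_dataset():
    """The 5-class study-condition dataset: 200 windows/class, 128 samples."""
    return generate(default_spec(n_classes=5, n_per_class=200, samples=128, seed=1))
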