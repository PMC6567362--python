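import numpy as np
import pytest

from motionwarp import MotionGeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """30 labeled synthetic sequences (10 per category), moderate noise."""
    cfg = MotionGeneratorConfig(seed=42, noise_sd=0.05)
    return generate_dataset(10, cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Well-separated sequences: no noise, keep speed variation."""
    cfg = MotionGeneratorConfig(seed=7, noise_sd=0.0, amplitude_jitter=0.0)
    return generate_dataset(8, cfg)
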