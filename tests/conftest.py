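import numpy as np
import pytest

from eegauth import SimConfig, generate_dataset
from eegauth.pipeline import PipelineConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """3 users, short runs — fast fixture for plumbing tests."""
    cfg = SimConfig(n_users=3, n_runs=4, n_train_runs=2, run_duration=6.0,
                    separation=1.0, noise_sd=0.5, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_dataset():
    """The high-separation stated world used by end-to-end checks:
    8 users, 8 channels, 256 Hz, 7 runs (3 train / 4 test)."""
    cfg = PipelineConfig(separation=2.0, noise_sd=1.0, run_duration=30.0,
                         seed=1)
    return simulate(cfg), cfg


@pytest.fixture()
def gauss_classes():
    """Two well-separated Gaussian classes in 10-D (means +-3, sd 1)."""
    rng = np.random.default_rng(42)
    n = 200
    x = np.vstack([rng.normal(-3.0, 1.0, (n, 10)), rng.normal(3.0, 1.0, (n, 10))])
    y = np.array([1] * n + [2] * n)
    return x, y
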