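import numpy as np
import pytest

from fedhar.pipeline import build_windows
from fedhar.synthetic import default_config, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects, 60 s each: streams plus segmented windows (no features)."""
    config = default_config(n_subjects=2, duration_s=60.0, bout_length_s=8.0, seed=11)
    streams = generate_dataset(config)
    windows = build_windows(streams, 5.0, 0.5, with_features=False)
    return config, streams, windows


@pytest.fixture(scope="session")
def feature_pool():
    """A pool of windows with attached, unscaled 161-feature vectors."""
    config = default_config(n_subjects=2, duration_s=90.0, bout_length_s=10.0, seed=29)
    streams = generate_dataset(config)
    return build_windows(streams, 5.0, 0.5, with_features=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
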