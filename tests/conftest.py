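import numpy as np
import pytest

from semgkit.synthetic import fast_config, generate


@pytest.fixture(scope="session")
def fast_ts():
    """Reduced-geometry synthetic trial set (5 classes x 12 trials, 8
    channels, 1 kHz, 1 s) shared across the end-to-end tests."""
    return generate(fast_config(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
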