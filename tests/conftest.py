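import numpy as np
import pytest

from frpbp import GeneratorConfig, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_record():
    """30 s noiseless-ish record used by several pipeline tests."""
    cfg = GeneratorConfig(duration=30.0, noise_sd=0.01, seed=7)
    return generate_record(cfg)
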