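import numpy as np
import pytest
from hypothesis import settings

import splinedetrend as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """A 10 s dual-axis synthetic recording with ground truth (shared)."""
    cfg = sd.SyntheticConfig(duration_s=10.0, snr_db=10.0, seed=7)
    rec, truth = sd.gen_recording(cfg)
    return cfg, rec, truth
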