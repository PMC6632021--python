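import numpy as np
import pytest

from cardiosense import NOISE_PRESETS, NoiseConfig, generate_record
from cardiosense.realtime import train_stream_models

FS = 500.0


@pytest.fixture(scope="session")
def clean_records():
    """Noise-free 65-beat records for the three classes."""
    return {
        label: generate_record(label, 65, noise=NOISE_PRESETS["none"])
        for label in ("NORMAL", "ST_ELEVATION", "T_INVERSION")
    }


@pytest.fixture(scope="session")
def noisy_record():
    return generate_record("NORMAL", 65, noise=NoiseConfig(seed=3))


@pytest.fixture(scope="session")
def stream_models():
    """Binary MI models trained once on synthetic data (shared: training
    takes a few seconds)."""
    return train_stream_models(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
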