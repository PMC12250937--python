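import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spikestream as ss

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def q20():
    """Quantized 300 Hz highpass at 20 kHz."""
    return ss.design_quantized(20000, 300.0)


@pytest.fixture(scope="session")
def det20():
    """Default detector: -50 uV threshold, 1.5 ms refractory, 20 kHz."""
    return ss.DetectorConfig(threshold_uV=-50.0, refractory_ms=1.5,
                             fs_hz=20000)


def make_noise_stream(n_headstages, n_channels_per_hs, n_frames, seed,
                      sigma_counts=80, fs_hz=20000):
    """Random raw stream + its sample matrix, for codec/engine tests."""
    rng = np.random.default_rng(seed)
    mat = rng.normal(0, sigma_counts,
                     (n_frames, n_headstages * n_channels_per_hs))
    mat = np.clip(np.rint(mat), -32768, 32767).astype(np.int16)
    header = ss.StreamHeader(fs_hz=fs_hz, n_headstages=n_headstages,
                             n_channels_per_hs=n_channels_per_hs)
    return ss.encode_stream(mat, header), mat, header
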