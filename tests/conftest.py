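import numpy as np
import pytest

from nck.core import Recording
from nck.synth import GeneratorConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(x, fs, region="HP"):
    """Wrap a 1-D or 2-D array as a Recording with 50-um channel spacing."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    depths = np.arange(x.shape[0]) * 50.0
    return Recording(x, fs, depths, region=region)


@pytest.fixture(scope="session")
def small_session():
    """A 2-min two-region session with bursts, SPWs and units (seed 11)."""
    cfg = GeneratorConfig(duration=120.0, seed=11, n_units=5,
                          coupling_gain=0.4, locking_kappa=2.0)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def quiet_config():
    """Low-noise single-region config used for detector ground-truth tests."""
    return GeneratorConfig(
        duration=300.0, seed=3, two_region=False, spw_rate=0.0, n_units=0,
        burst_peak_amplitude=60.0, background_rms=20.0,
        background_1overf_exponent=1.0, background_knee_hz=0.1)
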