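import numpy as np
import pytest
from hypothesis import settings

from coreleasekit import SynthConfig

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

#: reference CCK+ basket-cell parameter set used as generator ground truth
#: throughout the recovery tests (means of the reported cell population)
REFERENCE_CELL = {
    "v_rest": -56.9,      # mV
    "rm": 158.5,          # MΩ
    "tau_m": 20.8,        # ms
    "sag_index": 0.83,
    "threshold": -41.9,   # mV
    "amplitude": 57.4,    # mV
    "half_width": 0.74,   # ms
    "ahp": 10.3,          # mV
    "adaptation_ratio": 0.43,
}


@pytest.fixture
def ref_cell():
    return dict(REFERENCE_CELL)


@pytest.fixture
def cfg_noiseless():
    return SynthConfig(seed=1234, dt=5e-5, noise_sd=0.0)


@pytest.fixture
def make_cfg():
    def _make(seed=1234, noise_sd=0.0, dt=5e-5):
        return SynthConfig(seed=seed, dt=dt, noise_sd=noise_sd)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(99)
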