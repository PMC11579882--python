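import numpy as np
import pytest

from wearlab import synthetic as syn
from wearlab.config import PipelineConfig
from wearlab.kinetics import scale_body_model


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free default-condition trial configuration (4 cycles)."""
    return syn.SyntheticConfig(n_cycles=4, imu_noise_acc_sd=0.0,
                               imu_noise_gyro_sd=0.0)


@pytest.fixture(scope="session")
def clean_trial(clean_cfg):
    """(poses, imu, emg, truth, body) for the noise-free trial."""
    return syn.simulate_trial(clean_cfg)


@pytest.fixture(scope="session")
def noisy_cfg():
    """Default trial with the default sensor-noise levels."""
    return syn.SyntheticConfig(n_cycles=4)


@pytest.fixture(scope="session")
def noisy_trial(noisy_cfg):
    return syn.simulate_trial(noisy_cfg)


@pytest.fixture(scope="session")
def pipeline_cfg():
    cfg = PipelineConfig()
    cfg.synthetic.n_cycles = 4
    return cfg


@pytest.fixture(scope="session")
def body():
    return scale_body_model(1.775, 94.2)
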