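import numpy as np
import pytest

from affectfuse.fusion import simulate_dataset
from affectfuse.synth import CouplingSpec, RoiCoupling, SimulationConfig, default_coupling


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale session: 9 trials, 128 Hz EEG, 8^3 voxel grid."""
    return SimulationConfig(
        seed=7,
        n_trials=15,
        eeg_rate=128.0,
        volume_shape=(8, 8, 8),
        coupling=default_coupling((8, 8, 8), amplitude=0.5),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def eeg_session():
    """EEG-only material (no BOLD) with enough music trials for statistics."""
    from affectfuse.synth import generate_affect, generate_eeg, generate_schedule

    cfg = SimulationConfig(seed=21, n_trials=18, eeg_rate=128.0)
    schedule = generate_schedule(cfg)
    latent, reported = generate_affect(schedule, cfg)
    eeg = generate_eeg(latent, schedule, cfg)
    return cfg, schedule, latent, reported, eeg
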