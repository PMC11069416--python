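import numpy as np
import pytest

from nirsync.synthetic import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def fs() -> float:
    return 8.33


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Short-conversation session config used by several suites."""
    return SimulationConfig(n_dyads=4, phase_durations=(120.0, 20.0, 120.0), seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session(small_config, 0)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """All nuisance processes disabled: pure forward-model hemodynamics."""
    return SimulationConfig(
        n_dyads=2,
        phase_durations=(120.0, 20.0, 120.0),
        noise_sd=0.0,
        heartbeat_amp_od=0.0,
        drift_sd_od=0.0,
        artifact_rate_per_min=0.0,
        hbr_noise=0.0,
        stimulus_coupling={},
        mni_jitter_sd_mm=0.0,
        real_jitter_sd_cm=0.0,
        seed=21,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
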