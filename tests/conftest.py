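import dataclasses

import pytest

from barovar.simulate import SimConfig, simulate_beat_series, study_presets


@pytest.fixture(scope="session")
def so_sim() -> SimConfig:
    """Generator config of the sedentary (SO) study arm."""
    return study_presets()["SO"].sim


@pytest.fixture(scope="session")
def so_beats(so_sim):
    """One full 30-min simulated recording at the SO preset."""
    return simulate_beat_series(dataclasses.replace(so_sim, seed=42))


@pytest.fixture()
def short_sim() -> SimConfig:
    """A quiet 10-s configuration for fast structural tests."""
    return SimConfig(
        duration_s=10.0,
        mean_sbp=150.0,
        mean_pi=170.0,
        lf_amp_sbp=3.0,
        hf_amp_sbp=1.0,
        gain=0.5,
        noise_sd_sbp=1.0,
        noise_sd_pi=0.3,
        seed=1,
    )
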