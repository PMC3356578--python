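import numpy as np
import pytest

import circakit as ck


@pytest.fixture
def ld_schedule() -> ck.LightSchedule:
    """Open-ended 12:12 LD, lights on 07:00, 150 lux."""
    return ck.LightSchedule.ld()


@pytest.fixture
def dd_schedule() -> ck.LightSchedule:
    return ck.LightSchedule.ld(photoperiod_h=0.0, lux="DD")


@pytest.fixture
def noiseless_config() -> ck.SimulationConfig:
    """Fully deterministic animal: solid band, exact counts, no jitter."""
    return ck.SimulationConfig(
        count_model="deterministic",
        onset_jitter_sd_min=0.0,
        gap_mean_min=0.0,
        light_leak_frac=0.0,
        masking_coeff=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
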