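import numpy as np
import pytest

from sepsishrv import SimulationConfig, Window5Min


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Short artifact-free record with single-band LF modulation."""
    return SimulationConfig(
        record_duration=600.0,
        band_amplitudes={"ULF": 0.0, "VLF": 0.0, "LF": 50.0, "HF": 0.0},
        ectopic_rate=0.0,
        missed_beat_rate=0.0,
        mean_nn=800.0,
        mean_nn_sd=0.0,
    )


def make_window(values, start=0.0, mean_nn_ms=None):
    """Window5Min from raw interval values with cumulative end-times."""
    values = np.asarray(values, dtype=float)
    times = start + np.cumsum(values) / 1000.0
    return Window5Min(
        start=start, end=start + 300.0, values=values, times=times, retained=True
    )


@pytest.fixture
def random_window(rng):
    v = rng.normal(800.0, 50.0, 350)
    return make_window(v)
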