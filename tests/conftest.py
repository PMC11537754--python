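import numpy as np
import pytest

from hemiretina.preprocessing import ERPWaveform
from hemiretina.synthetic_data import GroundTruth
from hemiretina.timegrid import SRATE_HZ, T0_MS, times_ms


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def quiet_gt():
    """Ground truth with all randomness switched off (pure deterministic signal)."""
    return GroundTruth(
        noise_sd_uv=0.0,
        eye_noise_sd_uv=0.0,
        latency_jitter_sd_ms=0.0,
        between_subject_sd_uv=0.0,
        artifact_prob=0.0,
    )


def make_wave(values, pool="bilateral", label=None, n_trials=1):
    return ERPWaveform(
        values=np.asarray(values, dtype=float),
        srate_hz=SRATE_HZ,
        t0_ms=T0_MS,
        pool=pool,
        label=label,
        n_trials=n_trials,
    )


@pytest.fixture
def wave_factory():
    return make_wave


@pytest.fixture
def t_ms():
    return times_ms()
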