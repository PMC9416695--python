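import warnings

import numpy as np
import pytest
from hypothesis import settings

from adpipe.config import SimulationConfig
from adpipe.synth import generate_recording

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

# overlapping sympathetic bursts are routine at the AD rate; keep test
# output clean
warnings.filterwarnings("ignore",
                        message="overlapping bursts merged in ground truth")


@pytest.fixture(scope="session")
def clean_ecg_config():
    """Noise-free, metronomic 60 s rhythm at 300 bpm."""
    return SimulationConfig(duration_s=60.0, baseline_hr_bpm=300.0,
                            hr_sd_bpm=0.0, line_noise_amp=0.0,
                            broadband_noise_sd=0.0, skna_baseline_uv=0.0,
                            qrs_leak_uv=0.0, burst_rate_hz=(0.0, 0.0),
                            seed=1)


@pytest.fixture(scope="session")
def short_recording():
    """A 120 s recording with one AD episode, shared across tests."""
    cfg = SimulationConfig(duration_s=120.0, ad_episodes=[(60.0, 105.0)],
                           seed=7)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
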