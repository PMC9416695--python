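"""Simulate one multimodal recording session and write it to CSV.

Builds a 2-minute session with one AD episode: a 10 kHz electrode channel
(ECG + 500-1000 Hz sympathetic activity), tail-cuff blood pressure twice a
minute, skin temperature at 0.03 Hz and the trigger annotation.
"""

import warnings

warnings.filterwarnings("ignore", message="overlapping bursts.*")

import numpy as np

from adpipe.config import SimulationConfig
from adpipe.io import write_recording
from adpipe.synth import generate_recording

cfg = SimulationConfig(duration_s=120.0, ad_episodes=[(60.0, 105.0)], seed=1)
rec, truth = generate_recording(cfg)
out = write_recording(rec, "scratch/example-recording")

in_ad = rec.bp[(rec.bp.time_s >= 60) & (rec.bp.time_s < 105)]
base = rec.bp[rec.bp.time_s < 60]
print(f"waveform: {len(rec.waveform)} samples at {rec.fs_hz:.0f} Hz "
      f"({rec.duration_s:.0f} s), peak {np.max(np.abs(rec.waveform)):.2f} mV")
print(f"beats simulated: {len(truth.beat_times_s)} "
      f"(~{60 * len(truth.beat_times_s) / rec.duration_s:.0f} bpm)")
print(f"sympathetic bursts: {len(truth.burst_intervals_s)}")
print(f"SBP baseline {base.sbp.mean():.1f} mmHg, during AD "
      f"{in_ad.sbp.mean():.1f} mmHg (rise drives the gold-standard label)")
print(f"written to {out}/")
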