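"""Simulation configuration for synthetic multimodal recordings.

The configuration captures the acquisition geometry of the rodent
autonomic-dysreflexia (AD) protocol this pipeline targets: one electrode
channel sampled at 10 kHz carrying both the ECG and the high-frequency
(500-1000 Hz) skin sympathetic nerve activity (skNA), tail-cuff blood
pressure read twice a minute, skin temperature at 0.03 Hz, and scheduled
colorectal-distension trigger episodes during which AD physiology
(>= 20 mmHg systolic rise, bradycardia, elevated sympathetic bursting)
is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording session.

    Waveform amplitudes are in mV on the shared electrode channel; skNA
    amplitudes are given in uV and are converted internally (1 uV = 1e-3 mV).
    All rates are per second; pressures in mmHg; temperatures in deg C.
    """

    duration_s: float = 600.0
    fs_hz: float = 10_000.0
    # -- cardiac rhythm --
    baseline_hr_bpm: float = 300.0
    hr_sd_bpm: float = 15.0
    ad_hr_delta_bpm: float = -60.0       # AD bradycardia
    ad_hr_sd_scale: float = 0.5          # HRV reduction during AD
    # -- AD schedule --
    ad_episodes: Sequence[tuple[float, float]] = field(default_factory=list)
    # -- blood pressure (tail cuff, 2 readings / min) --
    bp_interval_s: float = 30.0
    sbp_baseline_mmhg: float = 110.0
    dbp_baseline_mmhg: float = 80.0
    bp_noise_sd_mmhg: float = 1.5
    ad_sbp_rise_mmhg: float = 25.0
    ad_dbp_rise_mmhg: float = 10.0
    # -- sympathetic bursting --
    burst_rate_hz: tuple[float, float] = (0.05, 0.5)   # (baseline, AD)
    burst_amp_uv: float = 3.0
    burst_dur_ms: float = 300.0
    skna_baseline_uv: float = 0.2        # band-limited noise floor (RMS)
    qrs_leak_uv: float = 1.0             # QRS interference into the skNA band
    # -- additive waveform noise --
    line_noise_amp: float = 0.05         # 60 Hz, mV
    # Broadband (white) noise spans the full 5 kHz bandwidth, so its in-band
    # share at 500-1000 Hz is ~sqrt(1/10) of this SD; 2 uV total keeps the
    # uV-scale nerve signal observable, as it must be for skNA recording.
    broadband_noise_sd: float = 0.002    # mV
    # -- temperature probe --
    temp_fs_hz: float = 0.03
    temp_baseline_c: float = 33.5
    temp_drift_sd_c: float = 0.02        # random-walk step SD
    ad_temp_delta_c: float = -0.5
    # -- reproducibility --
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        if self.fs_hz <= 0:
            raise InvalidConfigError("fs_hz must be positive")
        # the skNA band tops out at 1000 Hz; honour Nyquist
        if self.fs_hz < 2 * 1000.0:
            raise InvalidConfigError(
                "fs_hz must be at least 2 kHz to carry the 500-1000 Hz band"
            )
        if self.baseline_hr_bpm <= 0:
            raise InvalidConfigError("baseline_hr_bpm must be positive")
        for name in (
            "hr_sd_bpm", "bp_noise_sd_mmhg", "burst_amp_uv", "burst_dur_ms",
            "skna_baseline_uv", "qrs_leak_uv", "line_noise_amp",
            "broadband_noise_sd", "temp_drift_sd_c", "bp_interval_s",
            "temp_fs_hz",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if any(r < 0 for r in self.burst_rate_hz):
            raise InvalidConfigError("burst rates must be non-negative")
        episodes = sorted(tuple(e) for e in self.ad_episodes)
        for start, end in episodes:
            if not (0 <= start < end <= self.duration_s):
                raise InvalidConfigError(
                    f"AD episode ({start}, {end}) outside [0, {self.duration_s}]"
                )
        for (_, e0), (s1, _) in zip(episodes, episodes[1:]):
            if s1 < e0:
                raise InvalidConfigError("AD episodes must not overlap")
        self.ad_episodes = episodes

    # -- convenience ---------------------------------------------------
    def in_ad(self, t: float) -> bool:
        """Whether time ``t`` (s) falls inside a scheduled AD episode."""
        return any(s <= t < e for s, e in self.ad_episodes)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["ad_episodes"] = [list(e) for e in self.ad_episodes]
        d["burst_rate_hz"] = list(self.burst_rate_hz)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["ad_episodes"] = [tuple(e) for e in d.get("ad_episodes", [])]
        d["burst_rate_hz"] = tuple(d.get("burst_rate_hz", (0.05, 0.5)))
        return cls(**d)


def default_ad_config(seed: int = 0, duration_s: float = 600.0) -> SimulationConfig:
    """The default study configuration: three 60 s AD episodes per 10 min.

    Episodes are aligned to the 15 s analysis grid and leave a 180 s
    trigger-free lead-in that serves as the baseline period for burst
    thresholding and delta-feature references.
    """
    episodes = [(180.0, 240.0), (330.0, 390.0), (480.0, 540.0)]
    episodes = [(s, e) for s, e in episodes if e <= duration_s]
    return SimulationConfig(duration_s=duration_s, ad_episodes=episodes, seed=seed)
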