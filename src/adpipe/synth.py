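"""Synthetic multimodal recordings with ground truth.

The generator emulates the statistical structure of restrained-rat
recordings during induced autonomic dysreflexia (AD): a 10 kHz electrode
channel carrying an ECG plus band-limited (500-1000 Hz) sympathetic nerve
activity, tail-cuff blood pressure twice a minute, slow skin-temperature
drift, and scheduled trigger episodes during which systolic pressure rises
by >= 20 mmHg, heart rate drops, beat-to-beat variability shrinks and
sympathetic bursting intensifies.

ECG synthesis is template-based: a fixed sum-of-Gaussians P-QRS-T complex
stamped at stochastic beat times. This gives exact fiducial ground truth
(beat times, wave on/offsets) for validating detectors, at the cost of
clinical realism, which the pipeline does not need.

A separate tabular generator (:func:`generate_feature_table`) produces
labeled feature matrices with known informative/redundant/noise columns for
testing the feature-selection stage in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .config import SimulationConfig, InvalidConfigError

__all__ = [
    "MultiChannelRecording",
    "GroundTruth",
    "ECG_TEMPLATE",
    "TEMPLATE_FIDUCIALS_MS",
    "render_ecg_template",
    "simulate_ecg",
    "simulate_skna_component",
    "mix_channels",
    "simulate_bp",
    "simulate_temperature",
    "generate_recording",
    "generate_feature_table",
]

UV_PER_MV = 1000.0

# Sum-of-Gaussians beat template, rat-scaled: (center_ms, amplitude_mV, sd_ms).
# QRS width 20 ms; R amplitude 1 mV on the Lead-I analog channel.
ECG_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "P": (-45.0, 0.12, 8.0),
    "Q": (-6.0, -0.10, 2.0),
    "R": (0.0, 1.00, 3.0),
    "S": (6.0, -0.15, 2.0),
    "T": (55.0, 0.25, 12.0),
}

# Ground-truth fiducials (ms relative to R): Gaussian wave on/offsets at
# 2.5 sd from the wave center, QRS bounds at 2 sd beyond Q/S centers.
TEMPLATE_FIDUCIALS_MS: dict[str, float] = {
    "p_onset": -45.0 - 2.5 * 8.0,
    "p_peak": -45.0,
    "p_offset": -45.0 + 2.5 * 8.0,
    "qrs_onset": -6.0 - 2.0 * 2.0,
    "qrs_offset": 6.0 + 2.0 * 2.0,
    "t_onset": 55.0 - 2.5 * 12.0,
    "t_offset": 55.0 + 2.5 * 12.0,
}

# support of the rendered complex; >= 5 sd past every wave center so the
# truncation step is below 1e-8 mV (a shorter span leaves broadband
# splatter above the ECG's spectral support)
_TEMPLATE_SPAN_MS = (-90.0, 125.0)


@dataclass
class GroundTruth:
    """Per-recording oracle for detector tests."""

    beat_times_s: np.ndarray
    burst_intervals_s: list[tuple[float, float]]
    ad_intervals_s: list[tuple[float, float]]
    sbp_series: pd.DataFrame  # columns: time_s, sbp

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times_s, dtype=float)
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ValueError("beat times must be strictly increasing")
        for s, e in self.burst_intervals_s:
            if e < s:
                raise ValueError("burst interval has negative length")


@dataclass
class MultiChannelRecording:
    """Time-aligned raw channels of one session.

    ``waveform`` is the single electrode channel (mV) carrying both the ECG
    and the high-frequency skNA component; sparse channels are DataFrames
    with a ``time_s`` column; ``events`` are the trigger (colorectal
    distension) intervals.
    """

    waveform: np.ndarray
    fs_hz: float
    bp: pd.DataFrame           # time_s, sbp, dbp, map
    temperature: pd.DataFrame  # time_s, temp_c
    events: list[tuple[float, float]] = field(default_factory=list)
    subject: str = "sim-0"
    t0_s: float = 0.0

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.waveform)) / self.fs_hz


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def render_ecg_template(beat_indices: np.ndarray, n_samples: int,
                        fs_hz: float) -> np.ndarray:
    """Render the noise-free P-QRS-T train at the given R-sample indices."""
    lo = int(np.floor(_TEMPLATE_SPAN_MS[0] * 1e-3 * fs_hz))
    hi = int(np.ceil(_TEMPLATE_SPAN_MS[1] * 1e-3 * fs_hz))
    rel_t_ms = np.arange(lo, hi + 1) / fs_hz * 1e3
    template = np.zeros_like(rel_t_ms)
    for center, amp, sd in ECG_TEMPLATE.values():
        template += amp * np.exp(-0.5 * ((rel_t_ms - center) / sd) ** 2)
    out = np.zeros(n_samples)
    for k in np.asarray(beat_indices, dtype=int):
        a, b = k + lo, k + hi + 1
        ta, tb = max(a, 0), min(b, n_samples)
        if ta < tb:
            out[ta:tb] += template[ta - a: tb - a]
    return out


def _draw_beat_times(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Stochastic beat times from the piecewise HR schedule.

    RR intervals are Gaussian around 60/HR(t) with SD mapped from the
    configured beat-rate SD (dRR = 60/HR^2 * dHR); during AD the mean HR is
    shifted by ``ad_hr_delta_bpm`` and the SD scaled by ``ad_hr_sd_scale``.
    """
    times = []
    t = 0.1  # lead-in so the first complex is fully rendered
    while t < config.duration_s - 0.11:
        times.append(t)
        hr = config.baseline_hr_bpm
        sd_bpm = config.hr_sd_bpm
        if config.in_ad(t):
            hr = hr + config.ad_hr_delta_bpm
            sd_bpm = sd_bpm * config.ad_hr_sd_scale
        rr_mean = 60.0 / hr
        rr_sd = 60.0 * sd_bpm / hr**2
        rr = rr_mean if rr_sd == 0 else rng.normal(rr_mean, rr_sd)
        # keep intervals physiologically plausible (NN band is 100-500 ms)
        t += float(np.clip(rr, 0.120, 0.480))
    return np.asarray(times)


def simulate_ecg(config: SimulationConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the ECG portion of the channel.

    Returns ``(waveform_mv, beat_times_s)``; beat times are snapped to the
    sample grid so they are exact fiducials of the rendered waveform.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    beat_idx = np.round(_draw_beat_times(config, rng) * config.fs_hz).astype(int)
    beat_idx = beat_idx[beat_idx < n]
    wave = render_ecg_template(beat_idx, n, config.fs_hz)
    t = np.arange(n) / config.fs_hz
    if config.line_noise_amp > 0:
        wave += config.line_noise_amp * np.sin(2 * np.pi * 60.0 * t)
    if config.broadband_noise_sd > 0:
        wave += rng.normal(0.0, config.broadband_noise_sd, n)
    return wave, beat_idx / config.fs_hz


def _skna_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS white noise band-limited to 500-1000 Hz."""
    sos = signal.butter(4, [500.0, 1000.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def _poisson_times(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Burst onset times from the piecewise-constant Poisson schedule."""
    base, ad = config.burst_rate_hz
    edges = sorted({0.0, config.duration_s,
                    *(s for s, _ in config.ad_episodes),
                    *(e for _, e in config.ad_episodes)})
    times = []
    for a, b in zip(edges, edges[1:]):
        rate = ad if config.in_ad(a) else base
        if rate <= 0 or b <= a:
            continue
        k = rng.poisson(rate * (b - a))
        times.extend(rng.uniform(a, b, size=k))
    return np.sort(np.asarray(times))


def _merge_intervals(intervals: list[tuple[float, float]]
                     ) -> tuple[list[tuple[float, float]], bool]:
    merged: list[tuple[float, float]] = []
    overlapped = False
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            overlapped = True
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged, overlapped


def simulate_skna_component(config: SimulationConfig,
                            beat_times: np.ndarray | None = None,
                            rng: np.random.Generator | None = None
                            ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Synthesize the high-frequency sympathetic component of the channel.

    The component is a 500-1000 Hz noise carrier amplitude-modulated by a
    baseline floor, raised-cosine burst envelopes at Poisson times (baseline
    rate outside AD episodes, elevated rate inside), and, when ``beat_times``
    is given, Gaussian blips at each R peak emulating the QRS interference
    that leaks into the skNA band on a shared electrode.

    Returns ``(component_mv, burst_truth)``; amplitudes are configured in uV
    but the series is returned in mV so it can be summed sample-wise with the
    ECG. Overlapping bursts are merged in the truth list with a warning.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    fs = config.fs_hz
    dur_s = config.burst_dur_ms * 1e-3

    envelope_uv = np.full(n, config.skna_baseline_uv)
    truth: list[tuple[float, float]] = []
    for onset in _poisson_times(config, rng):
        a = int(round(onset * fs))
        b = min(int(round((onset + dur_s) * fs)), n)
        if a >= n:
            continue
        k = np.arange(b - a)
        envelope_uv[a:b] += config.burst_amp_uv * 0.5 * (
            1 - np.cos(2 * np.pi * k / max(b - a - 1, 1)))
        truth.append((onset, min(onset + dur_s, config.duration_s)))
    truth, overlapped = _merge_intervals(truth)
    if overlapped:
        warnings.warn("overlapping bursts merged in ground truth", stacklevel=2)

    if beat_times is not None and config.qrs_leak_uv > 0 and len(beat_times):
        t = np.arange(n) / fs
        sd = 3e-3
        for bt in np.asarray(beat_times):
            a = max(int((bt - 4 * sd) * fs), 0)
            b = min(int((bt + 4 * sd) * fs), n)
            envelope_uv[a:b] += config.qrs_leak_uv * np.exp(
                -0.5 * ((t[a:b] - bt) / sd) ** 2)

    component_uv = _skna_carrier(n, fs, rng) * envelope_uv
    return component_uv / UV_PER_MV, truth


def mix_channels(ecg: np.ndarray, hf_component: np.ndarray) -> np.ndarray:
    """Sum the ECG and high-frequency components into the single raw channel."""
    ecg = np.asarray(ecg, dtype=float)
    hf = np.asarray(hf_component, dtype=float)
    if ecg.shape != hf.shape:
        raise ValueError(f"channel length mismatch: {ecg.shape} vs {hf.shape}")
    return ecg + hf


def simulate_bp(config: SimulationConfig,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Tail-cuff pressure readings every ``bp_interval_s`` seconds.

    SBP/DBP are Gaussian around their baselines, shifted by the configured
    AD rises inside episodes; MAP uses the standard one-third pulse-pressure
    formula MAP = DBP + (SBP - DBP)/3.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration_s, config.bp_interval_s)
    in_ad = np.array([config.in_ad(t) for t in times])
    sbp = (config.sbp_baseline_mmhg + config.ad_sbp_rise_mmhg * in_ad
           + rng.normal(0, config.bp_noise_sd_mmhg, times.size))
    dbp = (config.dbp_baseline_mmhg + config.ad_dbp_rise_mmhg * in_ad
           + rng.normal(0, config.bp_noise_sd_mmhg, times.size))
    return pd.DataFrame({
        "time_s": times, "sbp": sbp, "dbp": dbp,
        "map": dbp + (sbp - dbp) / 3.0,
    })


def simulate_temperature(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Skin-temperature samples at ``temp_fs_hz``: random-walk drift plus an
    optional AD-locked step."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration_s, 1.0 / config.temp_fs_hz)
    drift = np.cumsum(rng.normal(0, config.temp_drift_sd_c, times.size))
    in_ad = np.array([config.in_ad(t) for t in times])
    temp = config.temp_baseline_c + drift + config.ad_temp_delta_c * in_ad
    return pd.DataFrame({"time_s": times, "temp_c": temp})


def generate_recording(config: SimulationConfig, subject: str = "sim-0"
                       ) -> tuple[MultiChannelRecording, GroundTruth]:
    """Full bundle: mixed waveform + sparse channels + trigger annotations."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in seeds]
    ecg, beat_times = simulate_ecg(config, rngs[0])
    hf, burst_truth = simulate_skna_component(config, beat_times, rngs[1])
    bp = simulate_bp(config, rngs[2])
    temp = simulate_temperature(config, rngs[3])
    rec = MultiChannelRecording(
        waveform=mix_channels(ecg, hf), fs_hz=config.fs_hz, bp=bp,
        temperature=temp, events=list(config.ad_episodes), subject=subject,
    )
    truth = GroundTruth(
        beat_times_s=beat_times, burst_intervals_s=burst_truth,
        ad_intervals_s=list(config.ad_episodes),
        sbp_series=bp[["time_s", "sbp"]].copy(),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# direct tabular generator for the selection stage
# ---------------------------------------------------------------------------

def generate_feature_table(n_rows: int, n_informative: int = 5,
                           n_noise: int = 31, n_redundant: int = 0,
                           effect_size: float = 2.0, class_balance: float = 0.5,
                           redundant_jitter_sd: float = 0.3,
                           seed: int = 0) -> tuple[pd.DataFrame, list[str]]:
    """Labeled feature matrix with known structure.

    Informative columns are unit-variance Gaussians whose class means differ
    by ``effect_size`` standard deviations; redundant columns are affine
    copies of informative parents with Gaussian jitter (default jitter keeps
    pairwise R^2 ~ 0.92 > 0.7); noise columns are class-independent.

    Returns the table (feature columns + a binary ``label`` column, 1 = AD
    analog) and the list of informative column names.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if n_informative + n_noise + n_redundant < 1:
        raise ValueError("at least one feature column required")
    if n_redundant > 0 and n_informative == 0:
        raise ValueError("redundant columns need informative parents")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_rows * class_balance))
    labels = np.zeros(n_rows, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    cols: dict[str, np.ndarray] = {}
    informative = [f"inf_{i}" for i in range(n_informative)]
    for name in informative:
        cols[name] = rng.standard_normal(n_rows) + effect_size * labels
    for j in range(n_redundant):
        parent = informative[j % n_informative]
        slope = rng.uniform(0.5, 2.0) * rng.choice([-1, 1])
        cols[f"red_{j}_{parent}"] = (
            slope * cols[parent] + rng.uniform(-1, 1)
            + rng.normal(0, redundant_jitter_sd * abs(slope), n_rows))
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.standard_normal(n_rows)
    table = pd.DataFrame(cols)
    table["label"] = labels
    return table, informative
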