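"""Windowed feature extraction.

All channels are cut into fixed, non-overlapping 15 s windows (half-open
[t, t+15)) and a 37-column feature vector is computed per window:

* ECG temporal: mean NN, heart rate, QRS and PR intervals, median NN, nn5,
  pnn5, covNN, RMSSD (short-window heart-rate-variability statistics).
* ECG spectral: power and band area of the rat-scaled LF (0.01-0.75 Hz) and
  HF (0.75-2.5 Hz) bands of the NN tachogram, plus their ratios.
* skNA temporal: average skNA, average iskNA, iskNA area, burst count,
  summed burst duration, summed burst area.
* skNA spectral: LF (0-2.5), HF (2.5-5) and VHF (5-10 Hz) powers/areas of
  the iskNA envelope and their ratios.
* Temperature: delta, mean, median. Blood pressure: delta SBP/DBP, mean
  SBP/DBP, MAP.

"Power" is the integral of the periodogram PSD over the band; "area" is
the integral of the magnitude spectrum (sqrt PSD) — related but distinct
summaries. Delta features are referenced to a per-subject trigger-free
baseline period. Sparse channels (BP at 2/min, temperature at 0.03 Hz) are
matched to windows by timestamp containment, falling back to the nearest
previous reading when a window holds none.

A 15 s window cannot resolve the 0.01 Hz lower LF edge (frequency
resolution ~0.067 Hz); the band is integrated as defined regardless, and
``window_len_s`` is configurable for longer spectral windows.

Missing values are NaN markers, never exceptions, so downstream row
filtering stays explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .ecg import BeatSeries, NN_MIN_MS, NN_MAX_MS
from .skna import BurstSet, SknaTrace
from .synth import MultiChannelRecording

__all__ = [
    "WindowSpec", "make_windows", "hrv_time_features", "hrv_spectral_features",
    "morphology_features", "skna_features", "skna_spectral_features",
    "bp_features", "temperature_features", "extract_feature_table",
    "FEATURE_COLUMNS", "EXTRA_FEATURE_COLUMNS", "HRV_BANDS", "SKNA_BANDS",
    "WINDOW_LEN_S",
]

WINDOW_LEN_S = 15.0

HRV_BANDS = {"lf": (0.01, 0.75), "hf": (0.75, 2.5)}
#: human-convention preset kept as an alternative configuration
HRV_BANDS_HUMAN = {"lf": (0.04, 0.15), "hf": (0.15, 0.4)}
SKNA_BANDS = {"lf": (0.0, 2.5), "hf": (2.5, 5.0), "vhf": (5.0, 10.0)}

FEATURE_COLUMNS = [
    # ECG temporal
    "mean_nn_ms", "heart_rate_bpm", "qrs_interval_ms", "pr_interval_ms",
    "median_nn_ms", "nn5", "pnn5", "cov_nn", "rmssd_ms",
    # ECG (HRV) spectral
    "hrv_lf_power", "hrv_hf_power", "hrv_lf_hf_ratio",
    "hrv_alf", "hrv_ahf", "hrv_alf_ahf_ratio",
    # skNA temporal
    "avg_skna_uv", "avg_iskna_uv", "auc_skna_uvs",
    "n_bursts", "burst_duration_s", "auc_bursts_uvs",
    # skNA spectral
    "skna_lf_power", "skna_hf_power", "skna_vhf_power", "skna_lf_hf_ratio",
    "skna_alf", "skna_ahf", "skna_avhf", "skna_alf_ahf_ratio",
    # temperature
    "delta_temp_c", "mean_temp_c", "median_temp_c",
    # blood pressure
    "delta_sbp_mmhg", "delta_dbp_mmhg", "mean_sbp_mmhg", "mean_dbp_mmhg",
    "map_mmhg",
]

EXTRA_FEATURE_COLUMNS = [
    "sdnn_ms", "qt_interval_ms", "st_interval_ms", "pr_segment_ms",
    "st_segment_ms",
]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open analysis window [start_s, end_s)."""

    start_s: float
    end_s: float

    def contains(self, t: float | np.ndarray) -> np.ndarray:
        return (np.asarray(t) >= self.start_s) & (np.asarray(t) < self.end_s)


def make_windows(duration_s: float, window_len_s: float = WINDOW_LEN_S,
                 t0_s: float = 0.0) -> list[WindowSpec]:
    """Tile [t0, t0+duration) with non-overlapping windows; the trailing
    remainder is dropped."""
    n = int(np.floor(duration_s / window_len_s))
    return [WindowSpec(t0_s + i * window_len_s, t0_s + (i + 1) * window_len_s)
            for i in range(n)]


# ---------------------------------------------------------------------------
# HRV
# ---------------------------------------------------------------------------

def hrv_time_features(nn_ms: np.ndarray) -> dict[str, float]:
    """Short-window time-domain HRV statistics from validated NN intervals.

    nn5 counts successive differences with |dNN| > 5 ms; pnn5 is that count
    as a percentage of the number of differences; covNN = SDNN / mean NN.
    With fewer than two intervals the variability statistics are NaN.
    """
    nn = np.asarray(nn_ms, dtype=float)
    out = {k: np.nan for k in ("mean_nn_ms", "heart_rate_bpm", "median_nn_ms",
                               "sdnn_ms", "cov_nn", "rmssd_ms", "nn5", "pnn5")}
    if nn.size == 0:
        return out
    out["mean_nn_ms"] = float(np.mean(nn))
    out["median_nn_ms"] = float(np.median(nn))
    out["heart_rate_bpm"] = 60_000.0 / out["mean_nn_ms"]
    if nn.size < 2:
        return out
    d = np.diff(nn)
    out["sdnn_ms"] = float(np.std(nn, ddof=1))
    out["cov_nn"] = out["sdnn_ms"] / out["mean_nn_ms"]
    out["rmssd_ms"] = float(np.sqrt(np.mean(d**2)))
    out["nn5"] = float(np.sum(np.abs(d) > 5.0))
    out["pnn5"] = 100.0 * out["nn5"] / d.size
    return out


def _band_integrals(x: np.ndarray, fs: float,
                    bands: dict[str, tuple[float, float]]
                    ) -> dict[str, tuple[float, float]]:
    """(power, area) per band: integral of the PSD and of the magnitude
    spectrum over the band, by trapezoid over periodogram ordinates."""
    freqs, psd = _signal.periodogram(x, fs=fs, detrend=False)
    out = {}
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            out[name] = (0.0, 0.0)
            continue
        power = float(np.trapezoid(psd[m], freqs[m]))
        area = float(np.trapezoid(np.sqrt(psd[m]), freqs[m]))
        out[name] = (power, area)
    return out


def _ratio(a: float, b: float) -> float:
    return a / b if b > 0 else np.nan


def hrv_spectral_features(nn_ms: np.ndarray, fs_interp_hz: float = 10.0,
                          bands: dict[str, tuple[float, float]] | None = None
                          ) -> dict[str, float]:
    """Band powers/areas of the NN tachogram.

    The tachogram is placed at the cumulative NN times, linearly
    interpolated to an even ``fs_interp_hz`` grid, mean-detrended, and
    summarized by periodogram band integrals. Requires >= 4 intervals.
    """
    bands = HRV_BANDS if bands is None else bands
    keys = ("hrv_lf_power", "hrv_hf_power", "hrv_lf_hf_ratio",
            "hrv_alf", "hrv_ahf", "hrv_alf_ahf_ratio")
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 4:
        return {k: np.nan for k in keys}
    t = np.cumsum(nn) / 1e3
    grid = np.arange(t[0], t[-1], 1.0 / fs_interp_hz)
    if grid.size < 4:
        return {k: np.nan for k in keys}
    tach = np.interp(grid, t, nn)
    tach = tach - np.mean(tach)
    integ = _band_integrals(tach, fs_interp_hz, bands)
    (lf_p, lf_a), (hf_p, hf_a) = integ["lf"], integ["hf"]
    return {
        "hrv_lf_power": lf_p, "hrv_hf_power": hf_p,
        "hrv_lf_hf_ratio": _ratio(lf_p, hf_p),
        "hrv_alf": lf_a, "hrv_ahf": hf_a,
        "hrv_alf_ahf_ratio": _ratio(lf_a, hf_a),
    }


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def morphology_features(fiducials: pd.DataFrame, fs_hz: float,
                        include_extras: bool = False) -> dict[str, float]:
    """Per-window medians of per-beat morphology intervals (ms).

    A beat contributes to an interval only when both of its fiducials were
    delineated; windows with no eligible beat yield NaN.
    """
    def med(a: str, b: str) -> float:
        if fiducials.empty or a not in fiducials or b not in fiducials:
            return np.nan
        d = (fiducials[b] - fiducials[a]).dropna()
        return float(np.median(d)) / fs_hz * 1e3 if len(d) else np.nan

    out = {
        "qrs_interval_ms": med("qrs_onset", "qrs_offset"),
        "pr_interval_ms": med("p_onset", "qrs_onset"),
    }
    if include_extras:
        out.update({
            "qt_interval_ms": med("qrs_onset", "t_offset"),
            "st_interval_ms": med("qrs_offset", "t_offset"),
            "pr_segment_ms": med("p_offset", "qrs_onset"),
            "st_segment_ms": med("qrs_offset", "t_onset"),
        })
    return out


# ---------------------------------------------------------------------------
# skNA
# ---------------------------------------------------------------------------

def skna_features(skna: np.ndarray, iskna: np.ndarray, fs_hz: float,
                  bursts: BurstSet | pd.DataFrame, window: WindowSpec
                  ) -> dict[str, float]:
    """Temporal skNA summaries over one window.

    ``skna``/``iskna`` are the window's samples of the (QRS-cleaned) band
    signal and its integrated envelope; bursts are attributed to the window
    containing their onset.
    """
    bdf = bursts.bursts if isinstance(bursts, BurstSet) else bursts
    inw = bdf[window.contains(bdf["onset_s"].to_numpy())] if len(bdf) else bdf
    return {
        "avg_skna_uv": float(np.mean(np.abs(skna))) if len(skna) else np.nan,
        "avg_iskna_uv": float(np.mean(iskna)) if len(iskna) else np.nan,
        "auc_skna_uvs": (float(np.trapezoid(iskna, dx=1.0 / fs_hz))
                         if len(iskna) else np.nan),
        "n_bursts": float(len(inw)),
        "burst_duration_s": float(inw["duration_s"].sum()) if len(inw) else 0.0,
        "auc_bursts_uvs": float(inw["auc_uv_s"].sum()) if len(inw) else 0.0,
    }


def skna_spectral_features(iskna: np.ndarray, fs_hz: float,
                           fs_resample_hz: float = 20.0,
                           bands: dict[str, tuple[float, float]] | None = None
                           ) -> dict[str, float]:
    """Band powers/areas of the iskNA envelope, after block-mean resampling
    to ``fs_resample_hz`` and mean detrending."""
    bands = SKNA_BANDS if bands is None else bands
    keys = ("skna_lf_power", "skna_hf_power", "skna_vhf_power",
            "skna_lf_hf_ratio", "skna_alf", "skna_ahf", "skna_avhf",
            "skna_alf_ahf_ratio")
    x = np.asarray(iskna, dtype=float)
    step = max(int(round(fs_hz / fs_resample_hz)), 1)
    m = (x.size // step) * step
    if m < 4 * step:
        return {k: np.nan for k in keys}
    y = x[:m].reshape(-1, step).mean(axis=1)
    y = y - np.mean(y)
    integ = _band_integrals(y, fs_hz / step, bands)
    (lf_p, lf_a) = integ["lf"]
    (hf_p, hf_a) = integ["hf"]
    (vhf_p, vhf_a) = integ["vhf"]
    return {
        "skna_lf_power": lf_p, "skna_hf_power": hf_p, "skna_vhf_power": vhf_p,
        "skna_lf_hf_ratio": _ratio(lf_p, hf_p),
        "skna_alf": lf_a, "skna_ahf": hf_a, "skna_avhf": vhf_a,
        "skna_alf_ahf_ratio": _ratio(lf_a, hf_a),
    }


# ---------------------------------------------------------------------------
# sparse channels
# ---------------------------------------------------------------------------

def associate_readings(df: pd.DataFrame, window: WindowSpec) -> pd.DataFrame:
    """Readings timestamped inside the window; if none, the nearest previous
    reading is carried forward. Empty frame when no reading precedes."""
    t = df["time_s"].to_numpy()
    sub = df[window.contains(t)]
    if len(sub):
        return sub
    prev = df[t < window.start_s]
    return prev.tail(1)


def bp_features(bp: pd.DataFrame, window: WindowSpec,
                baseline_sbp: float, baseline_dbp: float) -> dict[str, float]:
    """Window means of SBP/DBP/MAP plus deltas against the subject's
    trigger-free baseline means."""
    sub = associate_readings(bp, window)
    if not len(sub):
        return {k: np.nan for k in ("delta_sbp_mmhg", "delta_dbp_mmhg",
                                    "mean_sbp_mmhg", "mean_dbp_mmhg",
                                    "map_mmhg")}
    mean_sbp = float(sub["sbp"].mean())
    mean_dbp = float(sub["dbp"].mean())
    return {
        "delta_sbp_mmhg": mean_sbp - baseline_sbp,
        "delta_dbp_mmhg": mean_dbp - baseline_dbp,
        "mean_sbp_mmhg": mean_sbp,
        "mean_dbp_mmhg": mean_dbp,
        "map_mmhg": float(sub["map"].mean()),
    }


def temperature_features(temp: pd.DataFrame, window: WindowSpec,
                         baseline_temp: float) -> dict[str, float]:
    sub = associate_readings(temp, window)
    if not len(sub):
        return {k: np.nan for k in ("delta_temp_c", "mean_temp_c",
                                    "median_temp_c")}
    return {
        "delta_temp_c": float(sub["temp_c"].mean()) - baseline_temp,
        "mean_temp_c": float(sub["temp_c"].mean()),
        "median_temp_c": float(sub["temp_c"].median()),
    }


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def baseline_period(recording: MultiChannelRecording) -> WindowSpec:
    """The trigger-free reference span: recording start up to the first
    trigger event (the whole recording when there are no events)."""
    if recording.events:
        first = min(s for s, _ in recording.events)
        if first <= recording.t0_s:
            raise ValueError("no trigger-free baseline at recording start")
        return WindowSpec(recording.t0_s, first)
    return WindowSpec(recording.t0_s, recording.t0_s + recording.duration_s)


def extract_feature_table(recording: MultiChannelRecording, beats: BeatSeries,
                          bursts: BurstSet, skna: SknaTrace,
                          iskna: SknaTrace,
                          window_len_s: float = WINDOW_LEN_S,
                          include_extras: bool = False) -> pd.DataFrame:
    """One row per window with the full named feature set.

    ``skna`` is the QRS-cleaned band trace, ``iskna`` its integrated
    envelope; bursts must come from ``iskna``. Per-window failures surface
    as NaN cells, never exceptions.
    """
    fs = recording.fs_hz
    t0 = recording.t0_s
    windows = make_windows(recording.duration_s, window_len_s, t0)
    r_times = t0 + np.asarray(beats.r_peaks) / fs

    # NN pairs attributed to the window containing the first peak
    nn_all = np.diff(r_times) * 1e3
    nn_onset = r_times[:-1]
    valid = (nn_all >= NN_MIN_MS) & (nn_all <= NN_MAX_MS)

    fid = beats.fiducials
    base = baseline_period(recording)
    bsub = recording.bp[base.contains(recording.bp["time_s"].to_numpy())]
    tsub = recording.temperature[
        base.contains(recording.temperature["time_s"].to_numpy())]
    baseline_sbp = float(bsub["sbp"].mean()) if len(bsub) else np.nan
    baseline_dbp = float(bsub["dbp"].mean()) if len(bsub) else np.nan
    baseline_temp = float(tsub["temp_c"].mean()) if len(tsub) else np.nan

    rows = []
    for w in windows:
        i0 = int(round((w.start_s - t0) * fs))
        i1 = int(round((w.end_s - t0) * fs))
        m = w.contains(nn_onset) & valid
        nn = nn_all[m]
        row: dict[str, float] = {"window_start_s": w.start_s}
        row.update(hrv_time_features(nn))
        row.update(hrv_spectral_features(nn))
        if fid is not None and len(fid):
            infid = fid[w.contains(t0 + fid["r_peak"].to_numpy() / fs)]
        else:
            infid = pd.DataFrame()
        row.update(morphology_features(infid, fs, include_extras=True))
        row.update(skna_features(skna.samples[i0:i1], iskna.samples[i0:i1],
                                 fs, bursts, w))
        row.update(skna_spectral_features(iskna.samples[i0:i1], fs))
        row.update(temperature_features(recording.temperature, w,
                                        baseline_temp))
        row.update(bp_features(recording.bp, w, baseline_sbp, baseline_dbp))
        rows.append(row)

    cols = FEATURE_COLUMNS + (EXTRA_FEATURE_COLUMNS if include_extras else [])
    table = pd.DataFrame(rows)
    table = table[["window_start_s"] + cols]
    table.insert(0, "subject", recording.subject)
    return table
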