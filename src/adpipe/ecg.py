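"""ECG conditioning and beat extraction.

The conditioning chain mirrors the acquisition protocol: a 60 Hz notch for
line interference, a seventh-order Butterworth band-pass (0.01-30 Hz) for
movement artifact and high-frequency noise, and moving-average smoothing.
Beats are found with the Pan-Tompkins algorithm (band-pass, derivative,
squaring, moving-window integration, dual adaptive thresholds with
search-back), beat-to-beat intervals are validated against a 100-500 ms
physiologic band to give NN intervals, and per-beat fiducials (P, QRS
on/offset, T on/offset) are delineated with derivative-threshold searches
and a tangent T-offset.

All IIR filters are applied forward-backward (zero phase) so fiducial
timing is not skewed, and band-passes are designed as second-order sections:
the 0.01-30 Hz design at 10 kHz is numerically unusable in transfer-function
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from ._dsp import sliding_mean

__all__ = [
    "EcgTrace", "BeatSeries", "notch_filter", "bandpass_filter",
    "moving_average", "pan_tompkins", "validate_nn", "delineate_beats",
    "NN_MIN_MS", "NN_MAX_MS", "FIDUCIAL_COLUMNS",
]

NN_MIN_MS = 100.0
NN_MAX_MS = 500.0

FIDUCIAL_COLUMNS = ["p_onset", "p_peak", "p_offset",
                    "qrs_onset", "qrs_offset", "t_onset", "t_offset"]


@dataclass
class EcgTrace:
    """A uniformly sampled waveform segment (mV)."""

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.fs_hz

    def replace(self, samples: np.ndarray) -> "EcgTrace":
        return EcgTrace(samples, self.fs_hz, self.t0_s)


@dataclass
class BeatSeries:
    """Detected beats: R-peak sample indices, validated NN intervals and
    per-beat fiducials (sample indices, NaN where not found)."""

    r_peaks: np.ndarray
    fs_hz: float
    nn_intervals_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    fiducials: pd.DataFrame | None = None

    @property
    def r_times_s(self) -> np.ndarray:
        return np.asarray(self.r_peaks) / self.fs_hz


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def notch_filter(trace: EcgTrace, f0: float = 60.0, q: float = 30.0) -> EcgTrace:
    """Zero-phase IIR notch at ``f0`` Hz (power-line interference)."""
    if f0 >= trace.fs_hz / 2:
        raise ValueError(f"notch frequency {f0} Hz is at or above Nyquist")
    b, a = signal.iirnotch(f0, q, fs=trace.fs_hz)
    return trace.replace(signal.filtfilt(b, a, trace.samples))


def bandpass_filter(trace: EcgTrace, low: float = 0.01, high: float = 30.0,
                    order: int = 7) -> EcgTrace:
    """Zero-phase Butterworth band-pass of the stated order.

    The high cut is an SOS Butterworth low-pass applied forward-backward.
    The low cut cannot be realized directly: at 10 kHz a 0.01 Hz IIR
    high-pass has poles within ~1e-6 of z = 1 and is numerically broken
    even in second-order sections. Instead the sub-``low`` baseline is
    estimated on a decimated grid (100x the cut frequency) with the same
    order of Butterworth low-pass — well-conditioned there — interpolated
    back and subtracted, giving the complementary high-pass response. The
    whole chain is linear and removes DC asymptotically.
    """
    nyq = trace.fs_hz / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) at fs={trace.fs_hz}")
    sos_lp = signal.butter(order, high, btype="lowpass",
                           fs=trace.fs_hz, output="sos")
    y = signal.sosfiltfilt(sos_lp, trace.samples)

    fs_d = min(trace.fs_hz, 100.0 * low)
    step = max(int(round(trace.fs_hz / fs_d)), 1)
    if step == 1:
        sos_hp = signal.butter(order, low, btype="highpass",
                               fs=trace.fs_hz, output="sos")
        return trace.replace(signal.sosfiltfilt(sos_hp, y))
    n = y.size
    m = n // step
    if m < 3 * (2 * order + 1):
        # too short for a baseline estimate at this corner: remove the mean
        return trace.replace(y - np.mean(y))
    blocks = y[: m * step].reshape(m, step).mean(axis=1)
    sos_base = signal.butter(order, low, btype="lowpass",
                             fs=trace.fs_hz / step, output="sos")
    base = signal.sosfiltfilt(sos_base, blocks,
                              padlen=min(m - 1, 10 * (2 * order + 1)))
    centers = (np.arange(m) + 0.5) * step
    baseline = np.interp(np.arange(n), centers, base)
    return trace.replace(y - baseline)


def moving_average(trace: EcgTrace, width_samples: int) -> EcgTrace:
    """Centered moving mean; edge windows shrink; width 1 is the identity."""
    if width_samples <= 0:
        raise ValueError("width_samples must be >= 1")
    return trace.replace(sliding_mean(trace.samples, width_samples))


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------

def pan_tompkins(trace: EcgTrace, band: tuple[float, float] = (25.0, 75.0),
                 mwi_ms: float = 30.0, refractory_ms: float = 80.0
                 ) -> np.ndarray:
    """R-peak sample indices via the classical Pan-Tompkins stages.

    Band-pass -> derivative -> squaring -> moving-window integration
    (window about one QRS duration) -> dual adaptive thresholds with
    search-back. The default band is the classical human 5-15 Hz QRS band
    scaled by 5x to the ~20 ms rodent QRS (a 300 bpm rhythm has its
    fundamental at 5 Hz, inside the human band, which smears beats into a
    sinusoid). Detections are refined to the local extremum of the
    rectified waveform, which makes the result invariant to polarity.
    Flat or too-short input yields an empty array.
    """
    fs = trace.fs_hz
    if fs < 200:
        raise ValueError("pan_tompkins requires fs >= 200 Hz")
    x = trace.samples
    if x.size < int(0.4 * fs) or np.ptp(x) == 0:
        return np.empty(0, dtype=int)

    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    mwi = sliding_mean(deriv**2, max(int(mwi_ms * 1e-3 * fs), 1))

    refractory = int(refractory_ms * 1e-3 * fs)
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.empty(0, dtype=int)

    # adaptive dual thresholds (signal/noise running estimates)
    head = mwi[: min(mwi.size, int(2 * fs))]
    spki = float(np.max(head))
    npki = float(np.mean(head)) / 2
    accepted: list[int] = []
    rr_hist: list[float] = []
    pending: list[int] = []  # sub-threshold candidates for search-back

    def thresh1() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in cand:
        peak = mwi[idx]
        rr_avg = np.mean(rr_hist[-8:]) if rr_hist else None
        if peak > thresh1():
            if accepted and rr_avg and (idx - accepted[-1]) > 1.66 * rr_avg:
                # missed-beat search-back at the lower threshold
                back = [j for j in pending
                        if accepted[-1] + refractory < j < idx - refractory
                        and mwi[j] > 0.5 * thresh1()]
                if back:
                    j = max(back, key=lambda j: mwi[j])
                    rr_hist.append(j - accepted[-1])
                    accepted.append(j)
            if accepted:
                rr_hist.append(idx - accepted[-1])
            accepted.append(idx)
            spki = 0.125 * peak + 0.875 * spki
            pending = []
        else:
            npki = 0.125 * peak + 0.875 * npki
            pending.append(idx)

    if not accepted:
        return np.empty(0, dtype=int)

    # refine to the rectified-waveform extremum near each MWI peak
    env = np.abs(x - np.median(x))
    sm = sliding_mean(env, max(int(3e-3 * fs), 1))
    half = int(0.040 * fs)
    refined = []
    for idx in accepted:
        a, b = max(idx - half, 0), min(idx + half + 1, x.size)
        c = a + int(np.argmax(sm[a:b]))
        a2, b2 = max(c - half // 4, 0), min(c + half // 4 + 1, x.size)
        refined.append(a2 + int(np.argmax(env[a2:b2])))
    refined = np.unique(np.asarray(refined, dtype=int))
    return refined


def validate_nn(r_peaks: np.ndarray, fs_hz: float) -> np.ndarray:
    """Successive R-R differences (ms) kept only inside [100, 500] ms.

    Bounds are inclusive. With fewer than two peaks the result is empty.
    """
    r = np.asarray(r_peaks, dtype=float)
    if r.size < 2:
        return np.empty(0)
    nn = np.diff(r) / fs_hz * 1e3
    return nn[(nn >= NN_MIN_MS) & (nn <= NN_MAX_MS)]


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

def _settle_index(d: np.ndarray, start: int, step: int, thr: float,
                  run: int, lo: int, hi: int) -> float:
    """March from ``start`` in direction ``step`` until |derivative| stays
    below ``thr`` for ``run`` consecutive samples; returns the run index
    nearest ``start``, NaN if never."""
    if step > 0:
        seg = np.abs(d[start:hi]) < thr
    else:
        seg = (np.abs(d[lo:start + 1]) < thr)[::-1]
    if seg.size < run:
        return np.nan
    win = np.convolve(seg.astype(np.int8), np.ones(run, dtype=np.int8),
                      mode="valid")
    hits = np.flatnonzero(win == run)
    if hits.size == 0:
        return np.nan
    return start + step * int(hits[0])


def delineate_beats(trace: EcgTrace, r_peaks: np.ndarray,
                    qrs_window_ms: float = 60.0,
                    p_window_ms: tuple[float, float] = (70.0, 20.0),
                    t_window_ms: tuple[float, float] = (20.0, 100.0),
                    settle_frac: float = 0.03) -> pd.DataFrame:
    """Per-beat fiducials as sample indices (NaN = not found).

    QRS on/offset: from R outward, the first point where the absolute
    derivative settles below ``settle_frac`` of its local maximum for ~1 ms.
    P: the maximum in a pre-QRS window, with derivative-settle on/offsets.
    T: the maximum in a post-QRS window; T offset by the tangent method
    (steepest descending tangent after the T peak extrapolated to the local
    baseline), T onset by derivative settle. Beats whose search windows fall
    off the recording carry NaN and are excluded from dependent features.
    """
    x = trace.samples
    fs = trace.fs_hz
    n = x.size
    d = np.gradient(x) * fs
    ms = 1e-3 * fs
    run = max(int(1 * ms), 1)
    rows = []
    for r in np.asarray(r_peaks, dtype=int):
        rec: dict[str, float] = {c: np.nan for c in FIDUCIAL_COLUMNS}
        rec["r_peak"] = r
        w = int(qrs_window_ms * ms)
        a, b = r - w, r + w
        if a >= 0 and b < n:
            thr = settle_frac * np.max(np.abs(d[a:b]))
            rec["qrs_onset"] = _settle_index(d, r - run, -1, thr, run, a, r)
            rec["qrs_offset"] = _settle_index(d, r + run, +1, thr, run, r, b)
        pa, pb = r - int(p_window_ms[0] * ms), r - int(p_window_ms[1] * ms)
        if pa >= 0 and pb > pa:
            p = pa + int(np.argmax(x[pa:pb]))
            rec["p_peak"] = p
            pthr = settle_frac * np.max(np.abs(d[pa:pb]))
            lo = max(pa - int(30 * ms), 0)
            hi = min(pb + int(25 * ms), n)
            rec["p_onset"] = _settle_index(d, p - 1, -1, pthr, run, lo, p)
            rec["p_offset"] = _settle_index(d, p + 1, +1, pthr, run, p, hi)
        ta, tb = r + int(t_window_ms[0] * ms), r + int(t_window_ms[1] * ms)
        if tb < n and tb > ta:
            tpk = ta + int(np.argmax(np.abs(x[ta:tb])))
            tthr = settle_frac * np.max(np.abs(d[ta:tb]))
            rec["t_onset"] = _settle_index(d, tpk - 1, -1, tthr, run,
                                           max(ta - int(20 * ms), 0), tpk)
            # tangent method: steepest point on the descending limb
            seg = slice(tpk, min(tpk + int(60 * ms), n - 1))
            if seg.stop - seg.start > 2:
                j = seg.start + int(np.argmax(np.abs(d[seg])))
                slope = d[j]
                if slope != 0:
                    baseline = x[min(tb + int(10 * ms), n - 1)]
                    t_off = j + (baseline - x[j]) / slope * fs
                    if tpk < t_off < n:
                        rec["t_offset"] = t_off
        rows.append(rec)
    cols = ["r_peak"] + FIDUCIAL_COLUMNS
    fid = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return fid
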