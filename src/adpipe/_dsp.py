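"""Shared low-level numerics: O(n) sliding means and run detection."""

from __future__ import annotations

import numpy as np


def sliding_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    ``width`` is the nominal window length in samples; edge windows shrink
    to what fits inside the array, so the output has the same length as the
    input and a constant input is reproduced exactly. Implemented with a
    cumulative sum, O(n) regardless of width.
    """
    x = np.asarray(x, dtype=float)
    if width < 1:
        raise ValueError("window width must be >= 1 sample")
    n = x.size
    if n == 0 or width == 1:
        return x.copy()
    half_lo = (width - 1) // 2
    half_hi = width - 1 - half_lo
    c = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    if n > width:
        # interior: full windows, pure slicing
        out[half_lo:n - half_hi] = (c[width:] - c[:-width]) / width
    edge = min(max(half_lo, half_hi) + 1, n)
    idx = np.arange(edge)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    out[:edge] = (c[hi] - c[lo]) / (hi - lo)
    idx = np.arange(max(n - edge, 0), n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    out[idx] = (c[hi] - c[lo]) / (hi - lo)
    return out


def runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges [start, stop) of maximal True runs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))
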