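"""CSV/JSON/YAML interchange for recordings and analysis artifacts.

A recording is written as a directory of plain-text files: ``waveform.csv``
(time_s, amplitude_mv), ``bp.csv`` (time_s, sbp, dbp, map),
``temperature.csv`` (time_s, temp_c), ``events.csv`` (start_s, end_s,
label) and ``meta.yaml`` (subject, fs). Beat annotations, burst tables and
feature tables are single CSV files; selection results are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import BeatSeries
from .selection import SelectionResult
from .skna import BurstSet
from .synth import MultiChannelRecording

__all__ = [
    "write_recording", "read_recording", "write_beats", "read_beats",
    "write_bursts", "write_features", "read_features",
    "write_selection", "read_selection",
]


def write_recording(rec: MultiChannelRecording, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": rec.times_s, "amplitude_mv": rec.waveform}
                 ).to_csv(out / "waveform.csv", index=False)
    rec.bp.to_csv(out / "bp.csv", index=False)
    rec.temperature.to_csv(out / "temperature.csv", index=False)
    pd.DataFrame([{"start_s": s, "end_s": e, "label": "trigger"}
                  for s, e in rec.events]
                 ).to_csv(out / "events.csv", index=False)
    (out / "meta.yaml").write_text(yaml.safe_dump({
        "subject": rec.subject, "fs_hz": float(rec.fs_hz),
        "t0_s": float(rec.t0_s)}))
    return out


def read_recording(in_dir: str | Path) -> MultiChannelRecording:
    p = Path(in_dir)
    meta = yaml.safe_load((p / "meta.yaml").read_text())
    wave = pd.read_csv(p / "waveform.csv")
    events_df = pd.read_csv(p / "events.csv")
    events = [(float(r.start_s), float(r.end_s))
              for r in events_df.itertuples()] if len(events_df) else []
    return MultiChannelRecording(
        waveform=wave["amplitude_mv"].to_numpy(),
        fs_hz=meta["fs_hz"],
        bp=pd.read_csv(p / "bp.csv"),
        temperature=pd.read_csv(p / "temperature.csv"),
        events=events, subject=meta["subject"], t0_s=meta.get("t0_s", 0.0))


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    df = pd.DataFrame({"r_peak_idx": np.asarray(beats.r_peaks, dtype=int)})
    df["r_time_s"] = df["r_peak_idx"] / beats.fs_hz
    if beats.fiducials is not None and len(beats.fiducials):
        fid = beats.fiducials.drop(columns=["r_peak"], errors="ignore")
        df = pd.concat([df, fid.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)


def read_beats(path: str | Path, fs_hz: float) -> BeatSeries:
    df = pd.read_csv(path)
    from .ecg import validate_nn
    r = df["r_peak_idx"].to_numpy()
    fid_cols = [c for c in df.columns if c not in ("r_peak_idx", "r_time_s")]
    fid = df[fid_cols].copy() if fid_cols else None
    if fid is not None:
        fid.insert(0, "r_peak", r)
    return BeatSeries(r, fs_hz, validate_nn(r, fs_hz), fid)


def write_bursts(bursts: BurstSet, path: str | Path) -> None:
    bursts.bursts.to_csv(path, index=False)


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_selection(result: SelectionResult, path: str | Path) -> None:
    d = asdict(result)
    Path(path).write_text(json.dumps(d, indent=2, default=str))


def read_selection(path: str | Path) -> SelectionResult:
    d = json.loads(Path(path).read_text())
    d["trajectory"] = [tuple(t) for t in d.get("trajectory", [])]
    return SelectionResult(**d)
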