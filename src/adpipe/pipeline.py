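"""End-to-end orchestration: simulate -> condition -> extract -> prepare ->
select -> evaluate.

``process_recording`` runs the signal chain on one recording exactly as the
acquisition protocol prescribes: notch + 0.01-30 Hz band-pass + smoothing
for the ECG, Pan-Tompkins beats with NN validation and delineation, the
500-1000 Hz skNA derivation with QRS blanking, 100 ms integration, baseline
mean + 3 SD burst thresholding, and the 15 s windowed feature table.

``run_full_analysis`` assembles a multi-subject study (default: eight
simulated subjects of 10 minutes each, ~320 windows), labels windows with
the 20 mmHg gold standard, prepares/splits the table, runs the selection
cascade (t-test filter, correlation pruning, then RFE to five features) and
benchmarks the classifier roster on the full and reduced feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dataset as ds
from . import ecg as ecg_mod
from . import evaluate as ev
from . import features as ft
from . import selection as sel
from . import skna as skna_mod
from .config import SimulationConfig, default_ad_config
from .synth import GroundTruth, MultiChannelRecording, generate_recording

__all__ = ["ProcessedRecording", "StudyResult", "process_recording",
           "simulate_study", "run_full_analysis"]


@dataclass
class ProcessedRecording:
    """All signal-chain artifacts for one recording."""

    recording: MultiChannelRecording
    beats: ecg_mod.BeatSeries
    skna: skna_mod.SknaTrace      # qrs-removed band signal
    iskna: skna_mod.SknaTrace     # integrated envelope
    bursts: skna_mod.BurstSet
    features: pd.DataFrame


@dataclass
class StudyResult:
    """Outputs of the full analysis."""

    labeled: ds.LabeledTable
    plan: ds.SplitPlan
    selection_results: list[sel.SelectionResult]
    reduced_subset: list[str]
    consensus: pd.DataFrame
    report: ev.EvalReport


def process_recording(rec: MultiChannelRecording,
                      window_len_s: float = ft.WINDOW_LEN_S,
                      smoothing_ms: float = 5.0) -> ProcessedRecording:
    """Run the conditioning + extraction chain on one raw recording."""
    raw = ecg_mod.EcgTrace(rec.waveform, rec.fs_hz, rec.t0_s)
    cond = ecg_mod.notch_filter(raw)
    cond = ecg_mod.bandpass_filter(cond)
    cond = ecg_mod.moving_average(
        cond, max(int(smoothing_ms * 1e-3 * rec.fs_hz), 1))
    r_peaks = ecg_mod.pan_tompkins(cond)
    nn = ecg_mod.validate_nn(r_peaks, rec.fs_hz)
    fiducials = ecg_mod.delineate_beats(cond, r_peaks)
    beats = ecg_mod.BeatSeries(r_peaks, rec.fs_hz, nn, fiducials)

    band = skna_mod.derive_skna(raw)
    cleaned = skna_mod.remove_qrs_interference(band, r_peaks)
    iskna = skna_mod.integrate_skna(cleaned)

    base = ft.baseline_period(rec)
    i0 = int(round((base.start_s - rec.t0_s) * rec.fs_hz))
    i1 = int(round((base.end_s - rec.t0_s) * rec.fs_hz))
    thr, mean, sd = skna_mod.burst_threshold(iskna.samples[i0:i1], rec.fs_hz)
    bursts = skna_mod.detect_bursts(iskna, thr, baseline_mean_uv=mean,
                                    baseline_sd_uv=sd)

    table = ft.extract_feature_table(rec, beats, bursts, cleaned, iskna,
                                     window_len_s=window_len_s)
    return ProcessedRecording(rec, beats, cleaned, iskna, bursts, table)


def simulate_study(n_subjects: int = 8,
                   base_config: SimulationConfig | None = None,
                   seed: int = 0, delta_mmhg: float = 20.0
                   ) -> tuple[pd.DataFrame, pd.Series,
                              list[tuple[MultiChannelRecording, GroundTruth]]]:
    """Simulate and process a cohort; returns (features, labels, bundles).

    Each subject gets an independent child seed; windows are labeled
    per subject with the SBP gold standard before concatenation.
    """
    cfg = base_config if base_config is not None else default_ad_config()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    tables, labels, bundles = [], [], []
    for i, s in enumerate(child_seeds):
        sub_cfg = replace(cfg, seed=int(s % 2**31))
        rec, truth = generate_recording(sub_cfg, subject=f"sim-{i}")
        proc = process_recording(rec)
        lab = ds.label_windows(proc.features, rec.events, rec.bp,
                               delta_mmhg=delta_mmhg)
        tables.append(proc.features)
        labels.append(lab)
        bundles.append((rec, truth))
    features = pd.concat(tables, ignore_index=True)
    y = pd.Series(np.concatenate([l.to_numpy() for l in labels]),
                  name="label")
    return features, y, bundles


def run_full_analysis(n_subjects: int = 8,
                      base_config: SimulationConfig | None = None,
                      seed: int = 0, sigma: int = 5,
                      n_distractors: int = 0) -> StudyResult:
    """The complete benchmark: cohort simulation through classifier table.

    ``n_distractors`` appends that many class-independent Gaussian columns
    before preparation, emulating uninformative sensor channels that the
    selection stage must reject.
    """
    features, labels, _ = simulate_study(n_subjects, base_config, seed)
    fcols = [c for c in features.columns if c in ft.FEATURE_COLUMNS]
    if n_distractors:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        for j in range(n_distractors):
            features[f"distractor_{j}"] = rng.standard_normal(len(features))
        fcols = fcols + [f"distractor_{j}" for j in range(n_distractors)]
    labeled, plan = ds.prepare_dataset(features, labels, seed=seed,
                                       feature_columns=fcols)
    table = labeled.table
    y = table["label"]
    fcols = labeled.feature_columns

    t_res = sel.ttest_filter(table[fcols], y)
    c_res = sel.chi2_filter(table[fcols], y)
    corr_res = sel.correlation_filter(table[fcols])
    g_res = sel.gini_importance_filter(table[fcols], y, seed=seed)
    # cascade: univariate survivors, pruned for redundancy, then RFE
    cascade = [c for c in t_res.retained if c in corr_res.retained]
    if len(cascade) <= sigma:
        cascade = corr_res.retained
    rfe_res = sel.rfe_logistic(table[cascade], y, sigma=sigma, seed=seed)
    results = [t_res, c_res, corr_res, g_res, rfe_res]
    consensus = sel.consensus_report(results)
    reduced = rfe_res.retained

    report = ev.compare_models(table, y, plan,
                               {"full": fcols, "reduced": reduced},
                               seed=seed)
    return StudyResult(labeled, plan, results, reduced, consensus, report)
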