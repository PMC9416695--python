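"""Windowed feature math against hand values and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from adpipe.features import (FEATURE_COLUMNS, WindowSpec, bp_features,
                             extract_feature_table, hrv_spectral_features,
                             hrv_time_features, make_windows,
                             morphology_features, skna_features,
                             skna_spectral_features, temperature_features)
from adpipe.skna import BurstSet, SknaTrace
from adpipe.pipeline import process_recording


class TestWindows:
    @pytest.mark.parametrize("dur,expected", [(60.0, 4), (59.0, 3),
                                              (15.0, 1), (14.9, 0)])
    def test_window_count(self, dur, expected):
        assert len(make_windows(dur)) == expected

    def test_disjoint_and_ordered(self):
        ws = make_windows(90.0)
        for a, b in zip(ws, ws[1:]):
            assert a.end_s == b.start_s
            assert a.start_s < b.start_s


class TestHrvTime:
    def test_hand_computed_example(self):
        out = hrv_time_features(np.array([300.0, 310.0, 305.0]))
        assert out["rmssd_ms"] == pytest.approx(np.sqrt(62.5))
        assert out["nn5"] == 1
        assert out["pnn5"] == pytest.approx(50.0)
        assert out["median_nn_ms"] == pytest.approx(305.0)

    def test_constant_rhythm(self):
        out = hrv_time_features(np.full(10, 200.0))
        assert out["sdnn_ms"] == 0.0
        assert out["cov_nn"] == 0.0
        assert out["rmssd_ms"] == 0.0
        assert out["pnn5"] == 0.0
        assert out["heart_rate_bpm"] == pytest.approx(300.0)

    def test_single_interval_marks_variability_absent(self):
        out = hrv_time_features(np.array([250.0]))
        assert np.isnan(out["rmssd_ms"]) and np.isnan(out["pnn5"])
        assert out["mean_nn_ms"] == pytest.approx(250.0)

    def test_scaling_behavior(self):
        nn = np.array([200.0, 210.0, 190.0, 205.0])
        a, b = hrv_time_features(nn), hrv_time_features(2 * nn)
        for k in ("mean_nn_ms", "median_nn_ms", "sdnn_ms", "rmssd_ms"):
            assert b[k] == pytest.approx(2 * a[k])
        assert b["heart_rate_bpm"] == pytest.approx(a["heart_rate_bpm"] / 2)
        assert b["cov_nn"] == pytest.approx(a["cov_nn"])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            nn = rng.uniform(150, 400, size=rng.integers(5, 60))
            out = hrv_time_features(nn)
            d = np.diff(nn)
            assert out["rmssd_ms"] == pytest.approx(
                np.sqrt((d**2).mean()), rel=1e-9)
            assert out["pnn5"] == pytest.approx(
                100.0 * np.sum(np.abs(d) > 5) / d.size, rel=1e-9)
            assert out["cov_nn"] == pytest.approx(
                np.std(nn, ddof=1) / np.mean(nn), rel=1e-9)


class TestHrvSpectral:
    def test_pure_hf_modulation(self):
        # 1.5 Hz sinusoidal tachogram -> energy in the 0.75-2.5 Hz band
        t = np.arange(0, 15, 0.2)  # one NN per 200 ms
        nn = 200.0 + 10.0 * np.sin(2 * np.pi * 1.5 * t)
        out = hrv_spectral_features(nn)
        assert out["hrv_hf_power"] > 0
        total = out["hrv_lf_power"] + out["hrv_hf_power"]
        assert out["hrv_hf_power"] / total >= 0.80

    def test_constant_tachogram_zero_power(self):
        out = hrv_spectral_features(np.full(40, 200.0))
        assert out["hrv_lf_power"] == pytest.approx(0.0, abs=1e-12)
        assert out["hrv_hf_power"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_intervals_absent(self):
        out = hrv_spectral_features(np.array([200.0, 210.0]))
        assert all(np.isnan(v) for v in out.values())

    def test_band_power_bounded_by_variance(self, rng):
        nn = rng.uniform(180, 260, 75)
        out = hrv_spectral_features(nn)
        t = np.cumsum(nn) / 1e3
        grid = np.arange(t[0], t[-1], 0.1)
        tach = np.interp(grid, t, nn)
        var = np.var(tach - tach.mean())
        assert (out["hrv_lf_power"] + out["hrv_hf_power"]) <= var * 1.05


class TestMorphology:
    def test_known_qrs_width(self, clean_ecg_config):
        from adpipe.ecg import EcgTrace, delineate_beats, pan_tompkins
        from adpipe.synth import simulate_ecg
        wave, _ = simulate_ecg(clean_ecg_config)
        tr = EcgTrace(wave, clean_ecg_config.fs_hz)
        fid = delineate_beats(tr, pan_tompkins(tr))
        out = morphology_features(fid, clean_ecg_config.fs_hz)
        assert out["qrs_interval_ms"] == pytest.approx(20.0, abs=3.0)

    def test_empty_fiducials_absent(self):
        out = morphology_features(pd.DataFrame(), 10_000.0)
        assert np.isnan(out["qrs_interval_ms"])

    def test_median_invariant_to_beat_order(self, rng):
        fid = pd.DataFrame({
            "qrs_onset": [100.0, 2100.0, 4100.0],
            "qrs_offset": [300.0, 2290.0, 4310.0],
            "p_onset": [0.0, 2000.0, 4000.0],
        })
        shuffled = fid.sample(frac=1, random_state=1)
        a = morphology_features(fid, 10_000.0)
        b = morphology_features(shuffled, 10_000.0)
        assert a == b


def _empty_bursts():
    return BurstSet(1.0, pd.DataFrame(
        columns=["onset_s", "duration_s", "auc_uv_s"]))


class TestSknaFeatures:
    def test_no_bursts(self):
        w = WindowSpec(0.0, 15.0)
        out = skna_features(np.zeros(100), np.zeros(100), 10_000.0,
                            _empty_bursts(), w)
        assert out["n_bursts"] == 0
        assert out["burst_duration_s"] == 0.0
        assert out["auc_bursts_uvs"] == 0.0

    def test_constant_iskna(self):
        fs = 1000.0
        n = int(15 * fs)
        w = WindowSpec(0.0, 15.0)
        out = skna_features(np.full(n, 2.0), np.full(n, 2.0), fs,
                            _empty_bursts(), w)
        assert out["avg_iskna_uv"] == pytest.approx(2.0)
        assert out["auc_skna_uvs"] == pytest.approx(15 * 2.0, rel=1e-3)

    def test_matches_brute_force(self, rng):
        fs = 1000.0
        n = int(15 * fs)
        skna = rng.standard_normal(n)
        iskna = np.abs(rng.standard_normal(n))
        bursts = pd.DataFrame({"onset_s": [3.0, 9.0, 20.0],
                               "duration_s": [0.4, 0.2, 0.3],
                               "auc_uv_s": [1.0, 0.5, 0.9]})
        w = WindowSpec(0.0, 15.0)
        out = skna_features(skna, iskna, fs, bursts, w)
        assert out["avg_skna_uv"] == pytest.approx(np.abs(skna).mean(),
                                                   rel=1e-9)
        assert out["auc_skna_uvs"] == pytest.approx(
            np.trapezoid(iskna, dx=1 / fs), rel=1e-9)
        assert out["n_bursts"] == 2          # onset inside [0, 15)
        assert out["burst_duration_s"] == pytest.approx(0.6)
        assert out["auc_bursts_uvs"] == pytest.approx(1.5)


class TestSknaSpectral:
    def test_vhf_modulation_dominates(self):
        fs = 1000.0
        t = np.arange(int(15 * fs)) / fs
        iskna = 1.0 + 0.5 * np.sin(2 * np.pi * 7.0 * t)
        out = skna_spectral_features(iskna, fs)
        total = (out["skna_lf_power"] + out["skna_hf_power"]
                 + out["skna_vhf_power"])
        assert out["skna_vhf_power"] / total >= 0.70

    def test_zero_input_zero_power(self):
        out = skna_spectral_features(np.zeros(20_000), 1000.0)
        assert out["skna_lf_power"] == 0.0
        assert out["skna_vhf_power"] == 0.0

    def test_ratio_absent_when_hf_zero(self):
        out = skna_spectral_features(np.zeros(20_000), 1000.0)
        assert np.isnan(out["skna_lf_hf_ratio"])


class TestSparseChannels:
    def test_bp_arithmetic(self):
        bp = pd.DataFrame({"time_s": [2.0, 9.0], "sbp": [132.0, 136.0],
                           "dbp": [85.0, 87.0], "map": [100.0, 103.0]})
        out = bp_features(bp, WindowSpec(0.0, 15.0), 110.0, 80.0)
        assert out["delta_sbp_mmhg"] == pytest.approx(24.0)
        assert out["mean_sbp_mmhg"] == pytest.approx(134.0)

    def test_locf_fallback(self):
        bp = pd.DataFrame({"time_s": [2.0], "sbp": [120.0], "dbp": [80.0],
                           "map": [93.3]})
        out = bp_features(bp, WindowSpec(15.0, 30.0), 110.0, 80.0)
        assert out["mean_sbp_mmhg"] == pytest.approx(120.0)

    def test_no_readings_absent(self):
        bp = pd.DataFrame({"time_s": [], "sbp": [], "dbp": [], "map": []})
        out = bp_features(bp, WindowSpec(0.0, 15.0), 110.0, 80.0)
        assert np.isnan(out["mean_sbp_mmhg"])

    def test_delta_zero_on_baseline(self):
        bp = pd.DataFrame({"time_s": [2.0, 9.0], "sbp": [110.0, 110.0],
                           "dbp": [80.0, 80.0], "map": [90.0, 90.0]})
        out = bp_features(bp, WindowSpec(0.0, 15.0), 110.0, 80.0)
        assert out["delta_sbp_mmhg"] == pytest.approx(0.0)

    def test_temperature_values(self):
        temp = pd.DataFrame({"time_s": [1.0, 8.0],
                             "temp_c": [36.8, 37.2]})
        out = temperature_features(temp, WindowSpec(0.0, 15.0), 36.8)
        assert out["mean_temp_c"] == pytest.approx(37.0)
        assert out["delta_temp_c"] == pytest.approx(0.2)


class TestExtractTable:
    def test_shape_and_columns(self, short_recording):
        _, rec, _ = short_recording
        table = process_recording(rec).features
        assert len(table) == 8  # 120 s / 15 s
        assert list(table.columns) == ["subject", "window_start_s"] \
            + FEATURE_COLUMNS
        assert not table[FEATURE_COLUMNS].isna().all().any()

    def test_deterministic(self, short_recording):
        _, rec, _ = short_recording
        t1 = process_recording(rec).features
        t2 = process_recording(rec).features
        assert t1.equals(t2)

    def test_window_cells_match_single_feature_recomputation(
            self, short_recording):
        _, rec, _ = short_recording
        proc = process_recording(rec)
        table = proc.features
        w = WindowSpec(30.0, 45.0)
        i0, i1 = int(30 * rec.fs_hz), int(45 * rec.fs_hz)
        expect = skna_features(proc.skna.samples[i0:i1],
                               proc.iskna.samples[i0:i1], rec.fs_hz,
                               proc.bursts, w)
        row = table[table.window_start_s == 30.0].iloc[0]
        for k in ("avg_skna_uv", "avg_iskna_uv", "n_bursts"):
            assert row[k] == pytest.approx(expect[k], rel=1e-9)

    def test_time_shift_invariance(self, short_recording):
        _, rec, _ = short_recording
        t1 = process_recording(rec).features
        import dataclasses
        shifted = dataclasses.replace(
            rec, t0_s=rec.t0_s + 120.0,
            bp=rec.bp.assign(time_s=rec.bp.time_s + 120.0),
            temperature=rec.temperature.assign(
                time_s=rec.temperature.time_s + 120.0),
            events=[(s + 120.0, e + 120.0) for s, e in rec.events])
        t2 = process_recording(shifted).features
        assert np.allclose(t2["window_start_s"],
                           t1["window_start_s"] + 120.0)
        for c in FEATURE_COLUMNS:
            assert np.allclose(t2[c].to_numpy(), t1[c].to_numpy(),
                               rtol=1e-9, atol=1e-9, equal_nan=True), c
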