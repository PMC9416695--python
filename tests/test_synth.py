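"""Generator contracts: determinism, construction oracles, spectral purity."""

import numpy as np
import pytest
from scipy import signal

from adpipe.config import InvalidConfigError, SimulationConfig
from adpipe.synth import (generate_feature_table, generate_recording,
                          mix_channels, render_ecg_template, simulate_bp,
                          simulate_ecg, simulate_skna_component,
                          simulate_temperature)


def small_cfg(**kw):
    base = dict(duration_s=30.0, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_rejects_nonpositive_duration(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(duration_s=0)

    def test_rejects_out_of_range_episode(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(duration_s=100, ad_episodes=[(50, 120)])

    def test_rejects_overlapping_episodes(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(duration_s=100, ad_episodes=[(10, 40), (30, 60)])

    def test_yaml_roundtrip(self, tmp_path):
        cfg = small_cfg(ad_episodes=[(5.0, 10.0)])
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestSimulateEcg:
    def test_seeded_determinism(self):
        w1, b1 = simulate_ecg(small_cfg(seed=1))
        w2, b2 = simulate_ecg(small_cfg(seed=1))
        assert np.array_equal(w1, w2) and np.array_equal(b1, b2)

    def test_beat_count_at_fixed_rate(self):
        cfg = small_cfg(duration_s=60.0, baseline_hr_bpm=300.0, hr_sd_bpm=0.0)
        _, beats = simulate_ecg(cfg)
        assert abs(len(beats) - 300) <= 1

    def test_noise_free_waveform_is_pure_template_train(self):
        cfg = small_cfg(line_noise_amp=0.0, broadband_noise_sd=0.0)
        wave, beats = simulate_ecg(cfg)
        idx = np.round(beats * cfg.fs_hz).astype(int)
        ref = render_ecg_template(idx, wave.size, cfg.fs_hz)
        assert np.max(np.abs(wave - ref)) == 0.0

    def test_ad_episode_shifts_heart_rate(self):
        cfg = small_cfg(duration_s=120.0, ad_episodes=[(60.0, 120.0)],
                        hr_sd_bpm=0.0, ad_hr_delta_bpm=-60.0)
        _, beats = simulate_ecg(cfg)
        rr_base = np.diff(beats[(beats > 5) & (beats < 55)])
        rr_ad = np.diff(beats[(beats > 65) & (beats < 115)])
        assert rr_base.mean() == pytest.approx(60 / 300, abs=1e-3)
        assert rr_ad.mean() == pytest.approx(60 / 240, abs=1e-3)


class TestSknaComponent:
    def test_zero_rates_give_empty_truth(self):
        cfg = small_cfg(burst_rate_hz=(0.0, 0.0), qrs_leak_uv=0.0)
        comp, truth = simulate_skna_component(cfg)
        assert truth == []
        assert comp.size == int(cfg.duration_s * cfg.fs_hz)

    def test_poisson_burst_count(self):
        # E[n] = 0.05 * 50 + 0.5 * 50 = 27.5 over a 100 s half-AD run
        counts = []
        for s in range(6):
            cfg = SimulationConfig(duration_s=100.0,
                                   ad_episodes=[(50.0, 100.0)],
                                   burst_rate_hz=(0.05, 0.5), seed=s,
                                   qrs_leak_uv=0.0, burst_dur_ms=80.0)
            _, truth = simulate_skna_component(cfg)
            counts.append(len(truth))
        assert all(abs(c - 27.5) <= 3 * np.sqrt(27.5) for c in counts)

    def test_burst_power_confined_to_band(self):
        cfg = small_cfg(duration_s=20.0, burst_rate_hz=(0.5, 0.5),
                        skna_baseline_uv=0.05, qrs_leak_uv=0.0)
        comp, truth = simulate_skna_component(cfg)
        assert truth, "expected at least one burst"
        f, psd = signal.periodogram(comp, fs=cfg.fs_hz)
        total = np.trapezoid(psd, f)
        inband = np.trapezoid(psd[(f >= 500) & (f <= 1000)],
                              f[(f >= 500) & (f <= 1000)])
        assert inband / total >= 0.95

    def test_truth_intervals_inside_recording(self):
        cfg = small_cfg(burst_rate_hz=(0.4, 0.4))
        _, truth = simulate_skna_component(cfg)
        for a, b in truth:
            assert 0 <= a < b <= cfg.duration_s


class TestMixChannels:
    def test_zero_hf_is_identity(self, rng):
        ecg = rng.standard_normal(1000)
        assert np.array_equal(mix_channels(ecg, np.zeros(1000)), ecg)

    def test_commutative(self, rng):
        a, b = rng.standard_normal(500), rng.standard_normal(500)
        assert np.array_equal(mix_channels(a, b), mix_channels(b, a))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mix_channels(np.zeros(10), np.zeros(11))

    def test_band_split_recovers_components(self):
        cfg = small_cfg(duration_s=20.0, line_noise_amp=0.0,
                        broadband_noise_sd=0.0, burst_rate_hz=(0.5, 0.5),
                        qrs_leak_uv=0.0)
        ecg, beats = simulate_ecg(cfg)
        hf, _ = simulate_skna_component(cfg)
        mixed = mix_channels(ecg, hf)
        # split between the ECG's spectral support (the 2 ms Q/S waves
        # reach ~350 Hz) and the 500 Hz skNA band edge
        sos_lo = signal.butter(4, 400.0, btype="lowpass", fs=cfg.fs_hz,
                               output="sos")
        sos_hi = signal.butter(4, 400.0, btype="highpass", fs=cfg.fs_hz,
                               output="sos")
        ecg_rec = signal.sosfiltfilt(sos_lo, mixed)
        hf_rec = signal.sosfiltfilt(sos_hi, mixed)
        rel = lambda rec, ref: (np.sqrt(np.mean((rec - ref) ** 2))
                                / np.sqrt(np.mean(ref**2)))
        assert rel(ecg_rec, ecg) < 0.05
        assert rel(hf_rec, hf) < 0.05


class TestBloodPressure:
    def test_reading_count(self):
        bp = simulate_bp(small_cfg(duration_s=600.0))
        assert len(bp) == 20

    def test_map_formula(self):
        cfg = small_cfg(bp_noise_sd_mmhg=0.0, sbp_baseline_mmhg=130.0,
                        dbp_baseline_mmhg=85.0)
        bp = simulate_bp(cfg)
        assert np.allclose(bp["map"], 100.0)

    def test_ad_rise_applied(self):
        cfg = small_cfg(duration_s=600.0, ad_episodes=[(300.0, 420.0)],
                        ad_sbp_rise_mmhg=25.0)
        bp = simulate_bp(cfg)
        in_ad = bp[(bp.time_s >= 300) & (bp.time_s < 420)]
        noise_bound = 5 * cfg.bp_noise_sd_mmhg
        assert (in_ad["sbp"] >= cfg.sbp_baseline_mmhg + 25 - noise_bound).all()


class TestTemperature:
    def test_sample_count(self):
        temp = simulate_temperature(small_cfg(duration_s=600.0))
        assert len(temp) == 18

    def test_zero_drift_is_constant(self):
        cfg = small_cfg(temp_drift_sd_c=0.0)
        temp = simulate_temperature(cfg)
        assert np.allclose(temp["temp_c"], cfg.temp_baseline_c)

    def test_seeded_determinism(self):
        t1 = simulate_temperature(small_cfg(seed=9))
        t2 = simulate_temperature(small_cfg(seed=9))
        assert t1.equals(t2)


class TestGenerateRecording:
    def test_bundle_determinism(self):
        cfg = small_cfg(ad_episodes=[(10.0, 20.0)], seed=4)
        r1, t1 = generate_recording(cfg)
        r2, t2 = generate_recording(cfg)
        assert np.array_equal(r1.waveform, r2.waveform)
        assert r1.bp.equals(r2.bp)
        assert np.array_equal(t1.beat_times_s, t2.beat_times_s)

    def test_truth_matches_schedule(self):
        cfg = small_cfg(ad_episodes=[(10.0, 20.0)])
        rec, truth = generate_recording(cfg)
        assert truth.ad_intervals_s == [(10.0, 20.0)]
        assert rec.events == [(10.0, 20.0)]

    def test_channels_span_duration(self):
        cfg = small_cfg(duration_s=90.0)
        rec, truth = generate_recording(cfg)
        assert rec.duration_s == pytest.approx(90.0)
        assert rec.bp["time_s"].between(0, 90).all()
        assert rec.temperature["time_s"].between(0, 90).all()
        assert truth.beat_times_s.max() < 90.0


class TestFeatureTableGenerator:
    def test_determinism(self):
        t1, i1 = generate_feature_table(100, 3, 5, 2, seed=5)
        t2, i2 = generate_feature_table(100, 3, 5, 2, seed=5)
        assert t1.equals(t2) and i1 == i2

    def test_zero_jitter_redundant_is_exact_copy(self):
        tab, inf = generate_feature_table(200, 2, 0, 2,
                                          redundant_jitter_sd=0.0, seed=0)
        for col in [c for c in tab.columns if c.startswith("red_")]:
            parent = col.split("_", 2)[2]
            r = np.corrcoef(tab[col], tab[parent])[0, 1]
            assert r**2 == pytest.approx(1.0, abs=1e-12)

    def test_redundant_exceeds_r2_threshold(self):
        tab, inf = generate_feature_table(500, 3, 0, 3, seed=2)
        for col in [c for c in tab.columns if c.startswith("red_")]:
            parent = col.split("_", 2)[2]
            r = np.corrcoef(tab[col], tab[parent])[0, 1]
            assert r**2 > 0.7

    def test_negative_effect_size_rejected(self):
        with pytest.raises(ValueError):
            generate_feature_table(100, 2, 2, effect_size=-1.0)

    def test_informative_columns_separate_classes(self):
        # effect >= 2 SD at n = 500 must reject H0 essentially always
        from scipy import stats
        tab, inf = generate_feature_table(500, 5, 5, effect_size=2.0, seed=8)
        y = tab["label"]
        for c in inf:
            p = stats.ttest_ind(tab.loc[y == 1, c], tab.loc[y == 0, c]).pvalue
            assert p < 1e-6
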