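# Methods

`adpipe` implements an end-to-end analysis for detecting autonomic
dysreflexia (AD) — the episodic hypertensive reflex of high spinal cord
injury — from multimodal, non-invasive recordings: a single electrode
channel carrying both the ECG and skin sympathetic nerve activity (skNA),
tail-cuff blood pressure, and skin temperature. Because no recording of
this kind is publicly deposited, the package ships a first-class synthetic
generator that emulates the statistical structure of the restrained-rat
preparation, and every stage of the analysis is validated against the
generator's ground truth.

## The synthetic cohort

One session is parameterized by `SimulationConfig`. Defaults define the
study conditions and are rat-scaled:

| parameter | default | rationale |
|---|---|---|
| `fs_hz` | 10 000 | electrode digitization rate; must carry the 500–1000 Hz skNA band |
| `duration_s` | 600 | one 10-minute session |
| `baseline_hr_bpm` / `hr_sd_bpm` | 300 / 15 | rodent resting rate; RR ≈ 200 ms sits inside the 100–500 ms NN validation band |
| `ad_hr_delta_bpm` | −60 | baroreflex bradycardia during the hypertensive episode |
| `ad_hr_sd_scale` | 0.5 | beat-to-beat variability shrinks during AD |
| `sbp_baseline_mmhg` / `ad_sbp_rise_mmhg` | 110 / 25 | a rise comfortably above the 20 mmHg labeling threshold |
| `bp_interval_s` | 30 | tail-cuff readings twice a minute |
| `bp_noise_sd_mmhg` | 1.5 | measurement noise small enough that the labeling rule is decisive |
| `burst_rate_hz` | (0.05, 0.5) | Poisson rate of sympathetic bursts at rest vs. during AD |
| `burst_amp_uv` / `burst_dur_ms` | 3 / 300 | raised-cosine envelopes on a band-limited carrier |
| `skna_baseline_uv` | 0.2 | band-limited noise floor of the nerve channel |
| `qrs_leak_uv` | 1.0 | QRS interference leaking into the skNA band on the shared electrode |
| `line_noise_amp` | 0.05 mV | 60 Hz pickup |
| `broadband_noise_sd` | 0.002 mV | amplifier noise; white over 5 kHz it puts ~1/√10 of its SD into the skNA band, and a µV-scale nerve signal is only observable over a µV-scale in-band floor |
| `temp_fs_hz` | 0.03 | probe logging rate; drift is a small random walk with an AD-locked step of −0.5 °C |

The ECG is template-based: a fixed sum-of-Gaussians P-QRS-T complex (R
amplitude 1 mV, QRS width 20 ms) stamped at stochastic beat times drawn
from the piecewise heart-rate schedule. This trades clinical realism for
exact fiducial ground truth — the pipeline's validation needs known beat
times and wave boundaries, not a dynamical heart model. Template wave
on/offsets are defined at 2–2.5 Gaussian SDs from each wave center, and
the rendered support extends ≥5 SDs so truncation steps stay below 1e-8 mV
(shorter supports leave measurable broadband splatter).

The sympathetic component is amplitude-modulated band-passed white noise:
a unit-RMS 500–1000 Hz carrier multiplied by a baseline floor plus
raised-cosine burst envelopes at Poisson times, plus Gaussian blips at
each R peak emulating QRS interference. Bursts that overlap are merged in
the ground truth. The two components are summed sample-wise into the one
raw channel the pipeline ingests, exactly as a shared-electrode
acquisition mixes them.

The default cohort for the end-to-end benchmark is 8 subjects × 600 s with
three 60 s AD episodes each — 320 windows, a desk-scale analog of a
multi-animal study that keeps the full analysis under a few minutes on one
CPU. Subjects differ only by seed.

What the generator does **not** emulate: motion/restraint artifacts beyond
stationary broadband noise, tail-cuff measurement mechanics, per-subject
physiological heterogeneity, and — importantly — onset/offset latency of
the AD response (pressure, heart rate and bursting all switch as steps at
the episode boundaries). Consequences are discussed under *Limitations*.

## Signal conditioning and beat extraction

The ECG chain is: zero-phase 60 Hz IIR notch (Q = 30) → zero-phase
7th-order Butterworth band-pass 0.01–30 Hz → 5 ms moving-average
smoothing. All IIR filters run forward-backward so fiducial timing is not
skewed by filter phase.

The 0.01 Hz low cut deserves a note: at 10 kHz a 7th-order IIR high-pass
has poles within ~1e-6 of z = 1 and is numerically unusable even in
second-order sections (measured: broadband gain errors of tens of
percent). The implementation therefore applies the 30 Hz low-pass
directly, then estimates the sub-0.01 Hz baseline on a grid decimated to
100× the cut frequency (1 Hz) with the same-order Butterworth low-pass —
well-conditioned there — interpolates it back and subtracts. The chain is
exactly linear, removes DC asymptotically, and measures within 0.1 % of
unit gain at 10 Hz with >40 dB attenuation at 100 Hz. Signals too short
for a baseline estimate fall back to mean subtraction.

R peaks come from the classical Pan-Tompkins stages: band-pass →
derivative → squaring → 30 ms moving-window integration → dual adaptive
thresholds with missed-beat search-back. The QRS band-pass is the human
5–15 Hz band scaled ×5 to 25–75 Hz for the ~20 ms rodent QRS; at 300 bpm
the rhythm's 5 Hz fundamental sits inside the human band and smears beats
into a sinusoid (measured: systematic double detection). Detections are
refined to the extremum of the rectified waveform, making the detector
invariant to polarity. Successive R-R differences are kept as NN intervals
only inside the inclusive 100–500 ms physiologic band.

Delineation finds QRS on/offset by marching outward from R until the
absolute derivative settles below 3 % of its local maximum for 1 ms; the P
wave is the pre-QRS maximum with derivative-settle boundaries; the T
offset uses the tangent method (steepest descending tangent extrapolated
to the local baseline — for a Gaussian T wave this lands at exactly
2 SD past the center). On the noise-free template every fiducial lands
within ±10 ms of truth. Missing fiducials are NaN markers and the beat is
excluded from dependent interval features.

## skNA processing

The skNA band signal is the raw channel band-passed 500–1000 Hz
(Butterworth order 4 in second-order sections, zero phase; order 4 rather
than 2 because the design targets ≥40 dB at 60 Hz and 1.5 kHz and an
order-2 zero-phase response only reaches ~31 dB). QRS leakage is blanked
by replacing samples within ±50 ms of each R peak with a 5 ms running
median; samples outside those windows are bit-identical to the input.
iskNA is the sliding 100 ms **mean** of the rectified signal (the aSKNA
convention; the mean keeps µV units, and the paper-style sum is the mean
times a constant). The burst threshold is the mean + 3 SD of iskNA over
the rest baseline — by default the trigger-free span at the start of the
recording — and bursts are maximal supra-threshold runs lasting ≥100 ms
(the minimum suppresses single-sample crossings), reported with onset,
duration and trapezoidal area above threshold.

Burst count and total duration are monotone non-increasing in the
threshold for unimodal excursions (the generator's shapes); a multimodal
excursion can in principle split into two runs as the threshold rises.

## Windowed features

All channels are tiled into half-open, non-overlapping 15 s windows;
the trailing remainder is dropped. A burst or sparse reading belongs to
the window containing its onset/timestamp, so nothing is double-counted;
windows with no BP/temperature reading carry the nearest previous reading
forward (the channels are slower than the window: BP every 30 s,
temperature every 33 s).

Per window, 37 named features: HRV time statistics (mean/median NN, heart
rate, nn5/pnn5 with the >5 ms threshold, covNN, RMSSD), HRV band measures
on the NN tachogram interpolated to a 10 Hz grid and mean-detrended
(rat-scaled bands LF 0.01–0.75 Hz, HF 0.75–2.5 Hz; the human-convention
bands remain available as a preset), QRS/PR morphology medians, skNA
temporal measures (mean |skNA|, mean iskNA, iskNA area, burst count /
duration / area), iskNA band measures at 0–2.5 / 2.5–5 / 5–10 Hz after
block-mean resampling to 20 Hz, and temperature/pressure summaries with
Δ-features referenced to the subject's trigger-free baseline period.
"Power" is the integral of the periodogram PSD over the band; "area" is
the integral of the magnitude spectrum (√PSD) — related but deliberately
distinct summaries. SDNN and the QT/ST/PR-segment intervals are computed
as optional extras outside the default table.

The canonical column names, in table order (`adpipe.features.FEATURE_COLUMNS`):
`mean_nn_ms, heart_rate_bpm, qrs_interval_ms, pr_interval_ms, median_nn_ms,
nn5, pnn5, cov_nn, rmssd_ms, hrv_lf_power, hrv_hf_power, hrv_lf_hf_ratio,
hrv_alf, hrv_ahf, hrv_alf_ahf_ratio, avg_skna_uv, avg_iskna_uv,
auc_skna_uvs, n_bursts, burst_duration_s, auc_bursts_uvs, skna_lf_power,
skna_hf_power, skna_vhf_power, skna_lf_hf_ratio, skna_alf, skna_ahf,
skna_avhf, skna_alf_ahf_ratio, delta_temp_c, mean_temp_c, median_temp_c,
delta_sbp_mmhg, delta_dbp_mmhg, mean_sbp_mmhg, mean_dbp_mmhg, map_mmhg`;
optional extras: `sdnn_ms, qt_interval_ms, st_interval_ms, pr_segment_ms,
st_segment_ms`.

A 15 s window cannot resolve the 0.01 Hz LF lower edge (resolution
~0.067 Hz); the band is integrated as defined anyway and the window length
is configurable for longer spectral windows. Failures inside a window
surface as NaN cells, never exceptions.

## Dataset preparation

The gold-standard label is conjunctive: a window is AD only when it lies
inside a trigger episode **and** its associated SBP is ≥20 mmHg above the
subject's trigger-free baseline mean. Preparation order is fixed: label →
drop rows with missing values → remove rows where any feature's |z| > 3
(z on raw features; min-max scaling is affine so the decision is identical
either way) → min-max scale to [0, 1] (constant features map to 0 and are
flagged) → stratified 70/15/15 split with 10 stratified CV folds over the
training partition only. Splits are row-stratified; because windows from
one subject are correlated, row-level splitting leaks subject identity
across partitions — a caveat inherited from the protocol this mirrors.

## Feature selection

Five routes, each returning retained names, scores and parameters:

* **t-test filter** — per-feature two-sample test, Welch's
  unequal-variance form by default (a flag restores the pooled form),
  retaining p < 0.05 with no multiple-testing correction (deliberately:
  the downstream wrapper stages are the real gatekeepers).
* **chi-squared filter** — each feature discretized into quartile bins and
  tested against the label in a contingency table. The common count-style
  chi-squared score is badly uncalibrated on continuous scaled features
  (measured null retention ~0 at α = 0.05); the contingency form measures
  0.052, matching α.
* **correlation pruning** — iteratively examine the worst pair with
  pairwise R² > 0.7 and drop the member with the larger mean R² against
  the remaining features (ties drop the later column) until no pair
  offends.
* **Gini importance** — impurity-decrease importances from a seeded
  decision tree (or small forest), thresholded at the uniform share 1/p by
  default, optionally re-fitted recursively after each removal round.
* **Stepwise search / RFE** — greedy backward (or forward) moves scored by
  3-fold CV accuracy of logistic regression; and recursive feature
  elimination proper: repeatedly fit L2 logistic regression (C = 1),
  drop the smallest-|coefficient| feature, one per iteration, until σ
  remain. σ = 5 is the default reduced dimension.

`consensus_report` tabulates how many methods kept each feature. The
default cascade for the end-to-end run is: t-test survivors ∩
correlation-pruned survivors, then RFE down to 5. An exhaustive best-subset
enumerator exists for p ≤ 15 as a testing oracle only.

## Classifier benchmark

An eleven-model registry (k-NN, logistic regression, linear/RBF SVM,
Gaussian naive Bayes, QDA, decision tree, random forest, AdaBoost,
Gaussian process, MLP), each built seeded with recorded hyperparameters;
a 0.5-thresholded linear regression exists in the registry but is outside
the default roster. The MLP is the five-layer network: three hidden layers
(32, 32, 16), ~1 800 trainable parameters for a five-feature input, adam
with minibatches of 32, early stopping on an internal validation split
with a 50-epoch patience (full-batch adam with the library's 10-epoch
patience stalls at near-initial weights on few-hundred-row tables). QDA
uses reg_param = 0.1 because near-collinear scaled features make the raw
class covariances singular.

Models are fitted on the 70 % training rows and scored on the untouched
15 % test rows; the validation partition is reserved for early-stopping /
hyperparameter use. Metrics are the confusion-matrix identities (accuracy,
sensitivity, specificity, in percent) and ROC-AUC by the rank-statistic
(Mann–Whitney) formulation with ties counting one half. `compare_models`
crosses the roster with the full and reduced feature sets and appends an
explicit "neural-network (without feature selection)" alias row.

## Numerical choices

* Sliding means (smoothing, moving-window integration, iskNA) use an O(n)
  cumulative-sum implementation with shrinking edge windows, so constants
  are preserved and output length equals input length.
* 0-based sample indices; seconds for time; milliseconds for intervals;
  mV for the electrode channel; µV for skNA (converted at derivation).
* Ties in RFE and correlation pruning drop the later column; all
  stochastic steps take explicit seeds and identical inputs give
  bit-identical outputs.
* Degenerate inputs produce NaN markers (features) or empty results
  (detectors) rather than exceptions; genuinely invalid configuration
  raises.

## Limitations

* **Separability of the synthetic task.** The gold-standard label is a
  threshold on the same SBP channel that also produces the ΔSBP/mean-SBP
  features, and the generator switches all AD physiology as steps at
  episode boundaries. The default cohort is therefore (near-)perfectly
  separable and most classifiers sit at ceiling — useful for validating
  the machinery, but it means the benefit of feature selection shows up
  as parsimony (5 features matching 37+), not as the accuracy gap a
  noisier real cohort exhibits. In particular a full-feature neural
  network is not reliably worse than the reduced one here, because even
  with distractor columns appended it still finds the separating
  features. Emulating onset/offset latency of the pressor response and
  per-subject baseline heterogeneity would create the ambiguous
  boundary windows real data have; both are noted as future generator
  work and are deliberately not part of the present study conditions.
* Tests passing on this generator demonstrate algorithmic correctness
  against known ground truth, not clinical performance on rat or human
  recordings.
* The 15 s HRV spectral window under-resolves the LF band edge (above).
* Row-stratified splits leak subject identity (above); a group-aware
  split is the right choice when subjects differ.
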