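# adpipe

Multimodal physiological signal pipeline for detecting **autonomic
dysreflexia (AD)** — the episodic hypertensive reflex that threatens
people with spinal cord injury above T6. The package is aimed at
biomedical-signal researchers who need a tested, reproducible
implementation of the full analysis: signal conditioning, beat and
sympathetic-burst extraction, windowed feature engineering, a
feature-selection cascade, and a multi-classifier benchmark — together
with a synthetic-data generator that stands in for the (undeposited)
animal recordings and provides exact ground truth for every stage.

## What it computes

From a single electrode channel sampled at 10 kHz (ECG + skin sympathetic
nerve activity, skNA, sharing one lead), tail-cuff blood pressure at 2
readings/min, skin temperature at 0.03 Hz and trigger annotations:

* **Beats** — Pan-Tompkins QRS detection (band-pass → derivative →
  squaring → moving-window integration → adaptive thresholds), NN
  intervals validated to the physiologic band 100 ms ≤ NN ≤ 500 ms, and
  P/QRS/T delineation.
* **Bursts** — skNA = 500–1000 Hz band of the raw channel; QRS leakage
  blanked by a windowed running median; iskNA = 100 ms sliding mean of
  |skNA|; a burst is a ≥100 ms excursion above *mean + 3·SD* of the
  rest-period iskNA.
* **Features** — 37 per non-overlapping 15 s window: HRV statistics
  (meanNN, medianNN, HR = 60000/meanNN, RMSSD = √(mean ΔNN²), nn5/pNN5,
  covNN = SDNN/meanNN), tachogram band powers (LF 0.01–0.75 Hz,
  HF 0.75–2.5 Hz), QRS/PR morphology, skNA temporal and spectral
  measures, and BP/temperature summaries with Δ-features against the
  trigger-free baseline.
* **Labels** — the gold standard: AD ⇔ window inside a trigger episode
  **and** SBP ≥ baseline + 20 mmHg.
* **Selection** — t-test and chi-squared filters (p < 0.05), Pearson
  R² > 0.7 redundancy pruning, Gini-importance thresholding, greedy
  stepwise search, and recursive feature elimination with logistic
  regression down to σ = 5 features.
* **Evaluation** — eleven classifiers (k-NN … Gaussian process, 5-layer
  MLP with ~2,000 parameters) on a stratified 70/15/15 split, reported as
  confusion-matrix metrics (accuracy, sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP)) and rank-statistic ROC-AUC.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```sh
python examples/detect_beats.py
```

```
beats: 300 detected / 300 simulated, median timing error 0.20 ms
validated NN intervals: 299 (mean 199.4 ms -> 301 bpm)
RMSSD 14.53 ms, pNN5 77.2 % (beat-to-beat vagal-activity markers)
median QRS width 95.0 ms over 300 beats
```

A 60 s synthetic rat ECG at ~300 bpm is conditioned and every simulated
beat is recovered with sub-millisecond median timing error; the NN
statistics are the short-window HRV features the classifier later uses
(the QRS width is measured on the 0.01–30 Hz conditioned trace, which
broadens the raw 20 ms complex). The other scripts in `examples/` walk
through one capability each: simulation, burst quantification, feature
extraction, feature selection, and the full classifier benchmark
(`examples/benchmark_classifiers.py`, a few minutes).

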