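# lucisync

Rhythm detection and synchrony analysis for longitudinal bioluminescence
recordings of circadian reporters (e.g. PER2::LUC), built for three kinds
of data:

* **photomultiplier (PMT) traces** — counts per minute from freely moving
  animals in light-tight boxes, with shutter-closed dark-count intervals and
  a strongly growing baseline (in pregnant dams carrying reporter-positive
  conceptuses, total luminescence rises ~100-fold across gestation);
* **bioluminescence image stacks** — abdomen- or explant-facing camera
  frames, acquired on uneven schedules (twice daily early in gestation,
  every 4 h late; or every 30 min for cultured tissue), contaminated by
  cosmic-ray spikes and camera background;
* **tissue-explant luminometry** — 10-min-binned counts from cultured
  explants over ~5 days, damped oscillations on a drifting baseline.

The package answers the questions a circadian biologist asks of such data:
*is this trace circadian, and with what period, phase and amplitude?* and
*how synchronized are the oscillators — pixels within one animal, or
animals within a cohort?*

## The statistics at its core

**Rhythm classification.** A trace is detrended by subtracting its centred
24 h running mean, then tested by three detectors — a Lomb–Scargle
periodogram (uneven sampling allowed), a JTK-style Kendall-tau template
test, and harmonic regression with AR(1)-prewhitened residuals — whose
p-values are integrated by Fisher's statistic with a Brown dependence
correction. A trace is **circadian** if the integrated period T satisfies
18 h ≤ T ≤ 30 h with p < 0.05. Explant traces are instead summarized by a
least-squares damped cosine,

    y(t) = M + A·exp(−d·t)·cos(2π(t − t₀)/T),

fit to days 2–5, and called circadian when 18 ≤ T ≤ 30 h and the Pearson
correlation between fit and data exceeds 0.70. Peak-to-trough amplitude is
read off the 36–60 h window.

**Synchrony.** Per-pixel instantaneous phase θ_j(t) is read along the
maximal-power ridge of a complex Morlet continuous wavelet transform
(18–30 h band) after sinc detrending/smoothing. Synchrony within one
subject is the first-order Kuramoto order parameter

    r(t) = | (1/n) Σ_j exp(i·θ_j(t)) |  ∈ [0, 1],

and synchrony across subjects is the Rayleigh statistic R of their daily
peak times on the 24 h circle (R = 1: identical peak times; R → 0:
uniform), with the small-sample-corrected Rayleigh uniformity test.

A fully ground-truthed synthetic-data generator (`lucisync.synth`)
produces all three recording types — exponential baseline growth, logistic
onset of circadian modulation, per-pixel phase dispersion that collapses
over time, dark-count schedules, cosmic-ray spikes — so every estimator is
testable without any download.

## Worked example

```bash
python examples/explant_cosine_fit.py
```

```
period:        24.57 h   (truth 24.50)
peak phase:    ZT 12.25
amplitude:     297 counts (truth 300 at t=0)
damping rate:  0.0049 /h (truth 0.0050)
goodness r:    0.952
circadian:     True
peak-trough amplitude, 36-60 h window: 550 counts
```

A noisy simulated explant (true period 24.5 h, amplitude 300 counts,
damping 0.005/h) is recovered by the damped-cosine fit to within ~1% on
every parameter; `goodness` is the fit–data correlation that the r > 0.70
classification rule thresholds, and the final line is the empirical
peak-to-trough swing measured 36–60 h after recording onset.

The other scripts in `examples/` walk through the remaining capabilities:
`pmt_rhythm_detection.py` (dark-count subtraction, running-mean detrend,
meta rhythm test, daily peaks), `imaging_synchrony.py` (image pipeline and
the rising Kuramoto sync index), `inutero_study.py` (multi-dam study with
rule-based exclusion and inter-pregnancy Rayleigh R), and
`treatment_compare.py` (group mean ± SEM synchrony trajectories).

A thin CLI mirrors the pipeline stages:

```bash
lucisync simulate explant --out sim --seed 1
lucisync detect --trace sim/explant_trace.csv --method cosfit --out fit.json
lucisync rayleigh --peaks peaks.csv --out circ.json
lucisync run-inutero --config study.yaml --seed 0 --out report/
```

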