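# Methods

This note documents the models, estimators and numerical choices behind
`lucisync`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic tests
do and do not establish about real recordings.

## Data model and conventions

All time series carry timestamps in **hours from recording start**;
sampling may be uneven. Zeitgeber Time is anchored by `zt0_offset`, the
hours from recording start to the reference lights-on, so
ZT(t) = (t − zt0_offset) mod 24. Image coordinates are 0-based (row, col);
ROI and background masks are pixel-aligned and disjoint. Processing steps
that cannot produce valid values at the record edges mark samples invalid
(`valid_mask`) rather than pad: padding would fabricate data at exactly the
epochs (recording onset, rhythm emergence) the analyses score.

## Synthetic generator

The latent signal of one oscillating unit is

    I(t) = B₀ · exp(g·t) · (1 + a · s(t) · e^(−d·t) · cos(2π(t − t_peak)/T))

with baseline B₀, exponential growth rate g (the gestational ~100-fold
rise corresponds to g = ln(100)/duration), modulation depth a (fraction of
baseline), damping d, and a logistic onset ramp s(t) = 1/(1+exp(−(t−t₀)/τ))
with τ = 6 h. The logistic form was chosen because rhythm emergence in
these recordings is gradual; it is differentiable and has two
interpretable parameters (onset time, steepness). Two consequences are
documented rather than hidden: close to onset the ramp slope shifts local
maxima off the cosine peaks by up to ~0.3 h (the generator exposes
`peak_times_after_onset`, a numerical oracle for the true maxima), and a
24 h running mean applied across the onset is itself still ramping there.

**PMT traces.** Two sensors each see half the signal plus their own
dark-count rate (20 and 15 counts/min — absolute count scales for
luminometry are instrument-specific and the defaults are arbitrary); a
programmable-shutter schedule (default 1 min closed every 15 min) replaces
signal with dark counts and flags the samples. Noise is Poisson on
expected counts by default (physically motivated for photon counting),
with a Gaussian option for high-count regimes.

**Image stacks.** Each unit occupies a disc of pixels; every pixel shares
the unit's waveform with a peak-time offset drawn from N(0, σ_start h).
The offset scale shrinks toward σ_end over the record either linearly or
logistically (`dispersion_profile`); the logistic profile, with a midpoint
late in the record, is the synchronization scenario — coupling that
emerges mid-gestation — and is what the convergence tests use, because a
linear shrink leaves no valid (outside cone-of-influence) epoch at which
the start dispersion is still observable. Cosmic-ray spikes are
single-frame, single-pixel additions of ≥ 20× the local intensity
(amplitude 20 + Exp(10) times local signal), injected after the optional
point-spread blur, making the adjacent-frame-minimization guarantee
unambiguous. The mixed gestational acquisition (every 12 h, then every
4 h) is encoded as explicit timestamps, not a rate.

**Scales used in the packaged study scenarios.** The simulated multi-dam
study (`gestation_study`) uses 20×20-pixel frames with ~113 ROI pixels per
dam and switches to 4-h sampling at hour 96 of 216, leaving a fine-sampled
tail long enough that the wavelet's valid interior covers the
synchronization epoch; these sizes keep a full seven-dam study under ~10 s
while preserving every qualitative feature (growth, onset, convergence,
spikes, exclusion). Dams are modeled as entrained (period exactly 24 h,
peak times scattered ~N(ZT13, 1 h)); free-running period variation is an
explant phenomenon in this package.

## Preprocessing

* **Dark subtraction** estimates each sensor's dark level locally (mean of
  dark-interval samples in a centred 1 h window, interpolated across the
  record) so slow detector drift is tracked, then sums the two
  dark-corrected sensors and drops shutter-closed samples (the timestamp
  gap is retained).
* **Running-mean detrend** subtracts the exact time average of the trace's
  linear interpolant over a centred 24 h window (cumulative trapezoid with
  analytic edge handling). On a uniform grid this annihilates a pure 24 h
  cosine to machine precision and any linear ramp exactly, and it commutes
  with additive constants. Edge samples where the window does not fit are
  invalidated. For an exponential baseline the window curvature leaves a
  residual of about (g·w/2)²/6 of the local baseline (~1% at the
  gestational growth rate) — a property of the published procedure itself,
  verified, not corrected.
* **Sinc detrend/smooth** uses zero-phase windowed-sinc (Blackman) FIR
  low-passes: the trend is the low-pass at the detrend cutoff (default
  48 h), subtracted; the result is low-passed at the smooth cutoff
  (default 4 h). Defaults follow common wavelet-pipeline practice; both
  are exposed.
* **Image filters**: pixelwise adjacent-frame minimization (last frame
  pairs backward) removes single-frame events exactly — the filtered value
  falls back into the clean two-frame envelope; non-overlapping n-frame
  averaging (default 2, timestamps averaged, trailing partial block
  dropped); per-frame background subtraction by the mean of the background
  region; ROI photon flux as Σ(ROI) − |ROI|·mean(background); pixel series
  extraction after isotropic Gaussian smoothing (σ default 1 px, σ = 0 is
  the identity). For simulated stacks whose per-pixel phase offsets are
  spatially independent, σ = 0 is used in the packaged studies — spatial
  smoothing would average away exactly the heterogeneity under study; on
  real images, where phase is spatially structured, σ ≈ 1 px denoises
  without that cost.

## Rhythm detection

Three detectors feed the meta test, all scanning periods 18–30 h:

* **Lomb–Scargle**: classic periodogram on a period-uniform grid (0.05 h
  steps, parabolic peak refinement), peak power normalized by the sample
  variance, single-frequency tail (1 − 2z/(n−1))^((n−3)/2), and a
  Baluev-style extreme-value band correction
  p ≈ 1 − (1 − p₁)·exp(−W√z·e^(−z)) with W = Δf·√(4π·Var(t)). The simpler
  independent-frequency count was measurably anticonservative (~2× nominal
  in this narrow band).
* **JTK-style**: trace binned to a near-uniform grid (1 h), Kendall's tau
  against cosine templates over a period × phase-lag grid, one-sided p,
  Bonferroni over templates. Deliberately conservative; ties/constant
  data degrade to p = 1.
* **Harmonic + AR(1)**: per candidate period, OLS cosinor fit; the lag-1
  autocorrelation of its residuals is removed from response and design
  (prewhitening) and the amplitude F-test evaluated on the transformed
  system; best p gets the same band correction. Ties at saturated p are
  broken by variance explained.

**Integration.** The member p-values come from the same trace and are far
from independent, so Fisher's statistic X = −2Σlog pᵢ is referred to a
Brown-adjusted chi-square, c·χ²(f) with c = 2.63, f = 1.82, the moments of
X estimated once under a white-noise null on the canonical design (5 days,
10-min sampling, 1000 replicates) and frozen. Measured null rejection at
α = 0.05 is ≈ 0.04–0.06 across seeds; plain Fisher gave ≈ 0.14. Two-member
combinations use plain Fisher. The integrated period is the
−log(p)-weighted mean of member periods. Classification: circadian iff
18 ≤ T ≤ 30 h and p < α (strict), α default 0.05.

**Damped-cosine fit**: trust-region least squares of
M + A·e^(−d·t)·cos(2π(t−t₀)/T) on the fit window (default 48–120 h,
days 2–5), T bounded in (16, 32) h, A ≥ 0, 0 ≤ d ≤ 1/h, multi-started over
T ∈ {20, 22, 24, 26, 28} × phase ∈ {0, 6, 12, 18} h; lowest SSE wins.
Goodness is the Pearson correlation of fit vs data on the window;
classification 18 ≤ T ≤ 30 h and r > 0.70. `peak_phase_zt` is the ZT of
the model peak nearest the window midpoint — the phase actually identified
by a windowed fit; because A multiplies e^(−d·t) from recording start, A
alone is poorly identified on a late window (A–d degeneracy), while the
envelope at the window midpoint is recovered to a few percent at SNR 5.
Non-convergence or degenerate amplitude yields a flagged non-circadian
result, not an exception.

**Daily peaks**: ZT0-anchored 24 h windows; the (2 h-low-passed, when the
sampling supports it) series is scanned for interior local maxima;
candidates closer than 4 h merge keeping the larger (earlier on ties); the
winner is refined by quadratic interpolation through its neighbours. Days
with median sample spacing > 4 h (sparse early-gestation imaging), no
valid samples, or no interior maximum are omitted — a maximum clipped at a
window or validity edge is a boundary artifact, not a peak.

## Phase and synchrony

**Wavelet phase**: complex Morlet (bandwidth 2.0, centre frequency 1.0; in
ω₀ terms ≈ 6.3) over 60 scales spanning 18–30 h; the ridge is the per-time
power argmax and phase is the transform angle there, so phase 0 coincides
with the waveform maximum and is directly comparable with peak times.
Samples within 1.37 ridge periods of either record edge (the √2·scale
Morlet e-folding) are outside the cone of influence. Uneven inputs are
linearly interpolated to a 1 h grid first — the only resampling in the
package, and logged.

**Quality gate**: a pixel enters the synchrony pool only if the median
ridge power of its (detrended, smoothed) series exceeds the 95th
percentile of a variance-matched, filter-matched white-noise null (50
seeded replicates); pure-noise pixels otherwise bias the order parameter
downward.

**Kuramoto order parameter**: r = |mean exp(iθ)| over valid unit phases per
time point; undefined (error, not silently 1) below two units. The sync
time course additionally requires ≥ 90% of units inside the cone of
influence: near the edges the COI admits only the shortest-ridge-period
units, and r over that biased sliver is not comparable. With ~100 pixels
the per-sample noise on r is a few hundredths, so monotonicity of a
converging scenario is asserted in tests only up to a 0.05 tolerance after
smoothing.

**Circular statistics**: peak times map to angles via 2πt/24. Rayleigh
R/mean direction are the resultant of unit phasors (n = 1 is flagged
degenerate); the uniformity test uses Z = nR² with the standard
small-sample correction p = exp(√(1+4n+4(n²−Z n)) − (1+2n)), which matches
a simulated null within a few percent down to n = 6. Paired phase
differences wrap to (−12, 12] with circular-mean summaries.

## Study runners

`run_inutero` applies minimize → average → background → ROI flux →
running-mean detrend → meta test per dam; non-circadian dams are excluded
from peak and synchrony summaries but reported with machine-readable
reasons. Daily peaks of circadian dams feed per-day across-dam Rayleigh
summaries; pixel synchrony is computed on the fine-sampled (≤ 4 h) tail of
each stack, where instantaneous phase is estimable. `run_explant` fits
damped cosines, measures 36–60 h amplitudes, summarizes circadian peak
phases by a Rayleigh test and reports paired tissue phase differences.
`run_treatment_compare` reduces groups of stacks to mean ± SEM Kuramoto
trajectories on a common grid with a per-time group difference —
descriptive only; group inference (ANOVA families) is out of scope here.
Reports serialize to JSON and Markdown with the config hash, seed and
package version embedded; identical config + inputs reproduce
byte-identical reports.

## What the synthetic tests do and do not show

The generator reproduces the features the estimators must survive:
exponential baseline growth, gradual rhythm onset, uneven and mixed
sampling, shot noise, dark counts, camera background, cosmic-ray spikes,
and collapsing phase dispersion. It does not emulate spatial structure of
real tissue (per-pixel phase offsets are independent, so there are no
travelling waves and spatial smoothing is uninformative), animal-motion or
ROI-placement error, luciferin pharmacokinetics, or non-stationary periods
within a trace. Passing tests therefore certify the statistics and the
pipeline plumbing under realistic noise — not robustness to registration
error or biological period lability.

## Known limitations

* The Brown correction constants are calibrated on the canonical 5-day /
  10-min design; very different designs shift the member dependence
  somewhat (the direction of error is conservative for shorter records in
  the checks run here, but the constants are not design-adaptive).
* Wavelet phase near the cone of influence is biased toward later-epoch
  phase (zero-padding); the COI margin hides most but not all of it.
* The damped-cosine amplitude parameter A is reported at t = 0 by model
  convention; consumers comparing amplitudes should compare envelopes at a
  common in-window time.
* Daily peak extraction requires ≤ 4 h sampling within a day; the sparse
  twice-daily early-gestation segment yields no peak estimates by design.
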