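# Methods

This note documents the models, conventions, and numerical choices behind
`pwavekit`, and what the synthetic-data generator does and does not emulate.

## Time and state conventions

All times are seconds from recording start (float64). The hypnogram has a
2.5 s epoch; epoch *k* covers the half-open interval [2.5k, 2.5(k+1)), and an
event exactly on a boundary belongs to the later epoch (`floor(t/epoch)`).
States are Wake (W), NREM (N), intermediate sleep (I) and REM (R); IS is the
transitional state between NREM and REM, and the generator's Markov chain
forbids direct W→R and N→R transitions, so every REM episode is entered
through IS.

## Synthetic sessions (`pwavekit.synth`)

The generator is phenomenological: it reproduces the band powers, rates, and
event statistics that the downstream analyses assume, not biophysics.

* **Hypnogram.** A per-epoch Markov chain (state order W, N, I, R). The
  default self-transition probabilities encode geometric dwell times of
  roughly 60/120/20/75 s for W/N/I/R, giving a stationary mix of about
  21% wake, 56% NREM, 7% IS, 16% REM. `min_epochs` optionally enforces
  semi-Markov dwell minima (the 40 s NREM/REM, 15 s IS/wake filter used by
  transition analyses); with minima the chain's plain stationary distribution
  no longer applies, so the default leaves them at 1 epoch.
* **EEG/EMG.** Each EEG channel is 1/f background (20 µV SD) plus a
  band-limited delta process and a phase-integrated theta oscillator with
  state-dependent amplitudes (delta dominant in NREM, theta dominant in REM,
  both intermediate in IS), spindle packets (12–14 Hz) in NREM/IS (stronger
  frontally), and phasic theta bursts during REM (~0.06 bursts/s, 1–2.5 s,
  ×1.8 amplitude and +1.8 Hz). The theta oscillator's exact phase is kept so
  P-waves can be coupled to it. EMG is white noise with state-dependent tone
  (wake ≫ sleep; REM lowest) plus 50 ms twitch bursts locked to REM P-waves.
* **P-waves.** A difference-of-Gaussians biphasic template (default
  half-width 30 ms), trough depth 6× the raw LFP noise SD (0.015 mV), so
  events sit ~3 SD above the detection threshold after the 1–50 Hz band-pass
  (which attenuates the 1/f noise more than the fast template). Event times
  are state-dependent Poisson (defaults 0.6/0.15/0.02/0.01 events/s in
  R/I/N/W as *total* rates; the cluster-seed rate is deflated by the expected
  cluster multiplicity). A quarter of seeds spawn 1–3 companions at
  120–400 ms intervals. REM events are shifted (at most one theta cycle) to a
  von Mises phase (µ = −π/2, κ = 1.5) on the theta oscillator. Evoked events
  follow laser pulses with state-dependent success (0.91/0.91/0.66/0.34 for
  N/I/R/W) and gamma latency with mode 30 ms. A 100 ms minimum gap between
  events keeps detector candidates separable.
* **Photometry.** `465 = F₀(1 + ca)·B·(1 + m)`, `405 = F₀'·B·(1 + m)` with
  shared bleaching `B = exp(−t/τ)` (τ = 6000 s) and shared white motion noise
  (SD 0.003), so the isosbestic regression is exactly the right correction
  model. `ca` is a state baseline (REM 0.06, IS 0.02, else 0; smoothed by a
  2 s boxcar) plus per-P-wave transients with a Gaussian rise (SD 0.35 s)
  peaking 0.5 s after the event — the signal begins climbing ~0.4 s before
  the trough — and a 0.8 s exponential decay, amplitude 0.02 ΔF/F.
* **Laser.** Open loop: 120 s trains of 10 Hz pulses (10 ms up), gaps
  U(15, 25) min. Brief pulses: 10–20 ms, gaps U(10, 60) s. Closed loop: each
  REM episode independently laser-on with p = 0.5, 10 Hz pulses spanning the
  on-episodes.
* **Determinism.** Every stage draws from a named
  `SeedSequence(seed, spawn_key)` sub-stream, so a `SimConfig` with a fixed
  seed reproduces sessions bit-identically regardless of which stages run.

What the generator does **not** emulate: realistic EEG microstructure beyond
band power and burst statistics, artifacts (electrode noise, movement
spikes), inter-animal variability, circadian structure, and any
pharmacological kinetics. Passing round-trip tests therefore demonstrates the
correctness of the analysis chain under its stated assumptions, not detector
performance on noisy real-world recordings.

## Spectral estimation (`pwavekit.spectral`)

Spectrograms are consecutive Hann-windowed FFTs (per-window mean removal, no
other detrending, one-sided density scaling) at three presets: 5 s/50%
(2.5 s steps; scoring), 2 s/95% (100 ms; event-aligned), 2 s/80% (400 ms;
spectral field). Band power is the **mean** over in-band bins (bin membership
by center frequency, inclusive bounds), while EMG amplitude integrates
(sum × Δf, then square root) 10–500 Hz at the scoring preset or 10–100 Hz on
100 ms/50% windows for twitch analysis — the two conventions are deliberate
and documented because field usage differs between band summaries and EMG
"integration". Recording-mean normalization divides each frequency row by its
own session mean (idempotent; row means of 1); local normalization does the
same within a ±3 s event slab. Event slabs are centred on the nearest grid
column with lags reported on the canonical grid; slabs truncated at the
recording edge are dropped from averages, never zero-padded.

## Sleep scoring and closed-loop detection (`pwavekit.scoring`)

The offline scorer **emulates** manual criteria and makes no claim of scorer
equivalence. Per epoch: wake if the EMG amplitude exceeds its threshold (the
veto precedes everything), else REM if θ/δ exceeds the REM threshold, else IS
if θ/δ exceeds the IS threshold, else NREM; a 3-epoch majority filter removes
isolated labels. Thresholds are data-driven by default: a two-means split of
log EMG amplitude separates wake from sleep, a two-means split of the sleep
log θ/δ distribution separates NREM from the mixed IS+REM group, and a second
split of that group separates IS from REM. Hierarchical splitting matters —
a single split of θ/δ cannot isolate the small IS population. All thresholds
accept explicit overrides; on single-state recordings the data-driven splits
are meaningless and overrides should be used.

The closed-loop detector computes θ/δ and EMG amplitude on trailing 5 s
windows stepped by 2.5 s (matching the offline hypnogram resolution; the
online window length and update rate are free parameters). Onset requires one
supra-hard-threshold step (debounce configurable); the episode persists until
θ/δ < soft threshold or the EMG veto fires. Decisions are strictly causal;
detected intervals are timestamped at the onset of the epoch each decision
covers (the last full step inside the trailing window), which aligns
detections with the hypnogram clock and leaves a typical 1-epoch detection
delay relative to the true state change.

## P-wave detection (`pwavekit.pwave`)

Threshold statistics (mean, SD) are computed over the **entire** preprocessed
trace, all states included; users can pre-mask wake artifacts if needed. The
band-pass is an 8th-order zero-phase Butterworth (1–50 Hz), which rejects
60 Hz mains by ~27 dB. Sub-threshold runs separated by less than 50 ms of
supra-threshold signal are merged into one candidate (prevents
double-counting multiphasic troughs). Half-width is measured between the two
half-depth crossings with linear interpolation between samples. Amplitude and
half-width caps are applied **after** detection. Events in the (520, 780) ms
nearest-neighbour gap are labelled `unclassified` rather than forced into a
bin. Laser bookkeeping uses the half-open window (onset, onset + 100 ms] — an
event exactly at pulse onset is not attributed to the pulse; surrogate pulses
jitter REM pulses by U(−5, 5) s, re-clipped to their episode.

## Photometry and the spectral field (`pwavekit.photometry`)

The ΔF/F regression absorbs any common multiplicative gain and, with it, the
*mean* calcium level: the recovered trace equals the true ΔF/F up to a
1/(1 + mean ca) scale (a few percent at physiological signal sizes) and, when
bleaching is weak over a session, a small intercept tilt. Tests therefore
assert the exact limit (|ΔF/F| < 1e−6 when 465 = a·405) and profile recovery
at 10% relative tolerance rather than an absolute match.

The spectral field is fit by ridge regression on the lagged design matrix
(rows = spectrogram slabs of ±10 lags × in-band frequencies). The penalty
applies to H only; r₀ is absorbed by centring. One eigendecomposition of
XᵀX per fold serves the whole λ grid (logarithmic, 1e−3…1e4, 12 points by
default). Folds are contiguous blocks of the masked (REM) bins — shuffled
folds would leak autocorrelated samples between train and test. λ maximizes
the mean test-set R²; the model is then refit on all masked bins. With λ→0
and more bins than parameters the solution equals ordinary least squares to
machine precision; an underdetermined problem with λ = 0 raises instead of
silently pseudo-inverting. Whether the response is z-scored before fitting is
left to the caller (the fit is affine-equivariant through r₀).

Cross-correlation with the P-wave train uses 5 ms bins, REM episodes ≥ 30 s,
and per-episode normalization by the event count ("ΔF/F per event");
negative lags mean the ΔF/F leads. The jittered (±10 s) control spreads the
event-locked kernel into a smooth pedestal — flatness should be judged as
absence of sharp structure at the kernel lag, not as a zero trace.

## Event-aligned statistics (`pwavekit.events`)

Phase convention: phase 0 at the peak of the 6–12 Hz band-passed signal, so
the rising phase is (−π, 0) and the steepest rise is −π/2; troughs are ±π.
The Rayleigh test uses z = nR̄² with the standard small-sample series
correction (p clipped to [0, 1]); its type-I error is calibrated within
[0.03, 0.07] at α = 0.05 in the test suite. The spectral centroid is the
power-weighted mean frequency over 6–12 Hz (scale-invariant, bounded by the
band). Random control events are drawn uniformly within REM episodes,
count-matched, excluding ±0.5 s around real events. The pre-pulse predictor
window for laser-success correlations uses recording-mean normalization (the
event-slab scheme uses local normalization); the histogram default is 18 bins
(20°).

## Resampling inference (`pwavekit.bootstrap`)

Within-mouse resampling is per condition (mᵢ,on and mᵢ,off drawn
separately), matching the nested design. The equal-tail p-value uses the
(r+1)/(n+1) estimator, so the smallest attainable p at 10,000 iterations is
2·1/10001 ≈ 2.0e−4 and p is never 0. The percentile CI of the hierarchical
bootstrap slightly over-covers at n = 8 mice (≈97–98% empirical coverage at
nominal 95% in the calibration tests) — a known property of percentile
intervals on small hierarchical samples, left uncorrected because the
procedure itself is the method under test. Bootstrap p-values are reported
uncorrected for multiple comparisons; callers adjust.

## Problem sizes used in the checks

The round-trip tests and the acceptance script use one 2 h synthetic session
(the generator's default duration) for detection, scoring, photometry, and
closed-loop checks; 20 controlled simulations (8 frequencies × 11 lags,
~800 time bins) for spectral-field recovery at SNR 1; 200 replicates of
8 mice × 20 episodes at 10,000 bootstrap iterations for CI calibration; and
2000/500 simulations for Rayleigh type-I error and power. These sizes make
the whole suite runnable on a single CPU in a few minutes while keeping the
Monte Carlo error of each calibration well inside its acceptance band.

## Known limitations

* The scorer's data-driven thresholds assume all four states are present in
  reasonable proportion; degenerate recordings need explicit thresholds.
* The detector's threshold is global; long recordings with strongly
  non-stationary noise would benefit from blockwise statistics.
* The spectral-field fit assumes a stationary linear mapping within the
  masked state; it is a descriptive correlation tool, not a causal model.
* The bundle container stores raw series only; no vendor-format (Intan/TDT)
  parsing is included — conversion happens out of tree.
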