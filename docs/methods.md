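# Methods

## Pipeline model

The package treats individual identification from resting-state EEG as a
supervised multi-class problem over spectral feature vectors. One *trial* is
a 1-s epoch of an 18-channel recording (20 recorded channels minus the two
mastoids used as reference). Per trial, four feature tensors are computed:

* **PSD** (trials × 18 × 40): Welch's averaged modified periodogram,
  P̂(f) = (Δt / Σ hₙ²) |Σ hₙxₙe^(−j2πfn)|², evaluated at the DFT bins. The
  normalisation divides by the window power Σhₙ² so a white-noise input has
  the same expected level under any taper; with a rectangular window it
  reduces exactly to (Δt/N)|DFT|², which is the oracle identity the tests
  enforce to 1e-10.
* **Cross-spectrum** (trials × 171 × 40, complex): segment-averaged
  Xᵢ(f)·conj(Xⱼ(f)) for all pairs i ≤ j. The convention X·conj(Y) (as in
  MATLAB's `cpsd`) is used, so a positive phase at f means channel j lags
  channel i; SciPy's `csd` returns the complex conjugate of this. Amplitude
  is the modulus; phase is the argument of the *averaged* complex spectrum
  (never the average of per-segment arguments, which is wrap-around
  sensitive), with self-pairs pinned to exactly 0.
* **Coherence** (trials × 153 × 40): |P̂ₓᵧ|²/(P̂ₓₓP̂ᵧᵧ) over pairs i < j,
  clipped to [0, 1] against floating-point overshoot.

### Welch segmentation inside a 1-s epoch

NFFT = 100 at fs = 100 Hz fixes a 1-Hz bin grid, but a single 100-sample
segment per epoch would make every magnitude-squared coherence identically
1 (the single-segment estimator is degenerate). The default therefore uses
50-sample Hamming segments with 50% overlap, zero-padded to NFFT = 100 —
three inner segments per epoch, preserving the 1-Hz grid. The degenerate
single-segment configuration is accepted for PSD (where it is the plain
modified periodogram) but rejected with an explicit error for coherence.
With L independent segments the null expectation of coherence between
independent channels is ≈ 1/L; a Monte-Carlo test verifies the ≈ 1/2 and
≈ 1/8 levels at L = 2 and L = 8.

### Transforms, frequency axis, block averaging

Frequency bins are the integer-Hz bins 1..40 (DC excluded). PSD and
cross-spectrum amplitude are log₁₀-transformed with floor 1e-12; coherence
is Fisher-Z transformed as atanh(√C) with ceiling 1 − 1e-12; phase passes
through unchanged. After transformation, every 5 consecutive trials within
a (subject, run, condition) group are averaged (450 → 90 trials); blocks
never straddle group boundaries and a non-filling remainder is dropped with
a warning. Band selection uses inclusive endpoints, so the 8–13 and
13–20 Hz ranges share the 13 Hz bin; the 13-range catalogue spans θ, α, two
β ranges, low γ, seven combined ranges and the full 1–40 Hz benchmark.

## Preprocessing

Order is fixed: polyphase FIR resampling (Kaiser anti-aliasing) to 100 Hz →
mastoid re-reference ((M1+M2)/2 subtracted, mastoids dropped, channels
emitted in a frozen analysis order so pair indices are stable across files)
→ zero-phase 4th-order Butterworth band-pass 1–40 Hz (forward-backward, so
group delay never shifts epoch timing) → non-overlapping 1-s epochs with
the trailing partial second discarded. Re-referencing an already
18-channel recording raises a montage error rather than silently
re-projecting.

## Classification

The classifier is a linear-kernel SVM with C = 1 (scikit-learn `SVC`, which
trains one-vs-one binary machines for the multi-class problem), always
preceded by feature standardisation fitted on training data only (a
`Pipeline`, so cross-validation folds cannot leak test statistics). Splits:

* **intra-run** — stratified 10-fold CV within one run (90 trials/subject
  at full duration);
* **fusion** (F-RUN1 = runs 1+2, F-RUN2 = 1+3, F-RUN3 = 2+3, F-RUN4 =
  1+2+3) — trials pooled, stratified 10-fold CV, so each fold mixes data
  from the constituent runs in expectation;
* **inter-run transfer** (COND1 = train{1,2}/test{3}, COND2 =
  train{1,3}/test{2}, COND3 = train{2,3}/test{1}) — fit once, score on the
  held-out run. Since no hyperparameter is tuned (C is fixed), the
  train/validation distinction collapses to training.

Trials entering classification are the 90 block-averaged trials; evaluation
is per condition (separate REO and REC models). Accuracies are percentages
in [0, 100]; every catalogue cell is either populated or carries an
explicit skip reason (e.g. a single-subject input).

## Synthetic cohort generator

Because no public recordings accompany this problem, the generator is a
first-class, tested module that emulates the statistical structure the
analysis relies on — not the physiology. Each channel is a linear mixture
of latent sources plus independent sensor noise:

* six band-limited oscillators (2nd-order Butterworth-filtered white noise,
  unit variance) at θ 6 Hz, a subject-specific alpha peak in [8, 13] Hz, a
  posterior rhythm at 12.5 Hz, β 16.5 and 25 Hz, γ 35 Hz, with relative
  amplitudes decreasing with frequency;
* two broadband low-frequency latents (AR(1)-smoothed noise, pole 0.95)
  giving the 1/f-like dominance of low frequencies;
* per-channel white sensor noise.

A subject's *fingerprint* is (alpha peak, per-channel per-source power
gains, 20 × 8 mixing matrix, per-channel noise floor), drawn as a shared
cohort base plus a subject deviation scaled by `fingerprint_strength`
(default 1; 0 collapses all subjects onto the base — the null cohort).
`discriminative_band=(lo, hi)` zeroes the deviations of sources whose
center lies outside the window, confining the identity signal in frequency
(used to demonstrate band selectivity). Everything is a deterministic
function of the cohort seed and the (subject, run, condition) indices, via
keyed `SeedSequence` spawning.

**Condition effect.** Eyes-closed recordings multiply the variance of
sources centred in 10–15 Hz (the 12.5 Hz posterior rhythm, plus the alpha
source when its peak falls in that window) by 2.0. The measured
channel-level REC/REO power ratio in 10–15 Hz is ≈ 1.4 rather than 2.0
because other sources and sensor noise also contribute power in that band.

**Session drift.** Each (subject, run) draws log-normal multiplicative
jitter on the band gains and noise floor, with log-sd `run_drift`. Drift is
constant within a run, so intra-run CV is unaffected while inter-run
transfer degrades. The default `run_drift = 0.8` (power gains jittered by
roughly a factor 2 between sessions) was calibrated once so the drift
mechanism visibly separates transfer from intra-run accuracy at the default
fingerprint strength; real inter-session drift is not quantified anywhere,
so this is a modelling choice, not an estimate.

**What the generator does not emulate:** ocular/muscle artifacts,
non-stationarity within a session, volume-conduction geometry, electrode
impedance dynamics, or realistic inter-subject covariance of head anatomy.
Passing tests therefore demonstrate that the *pipeline* recovers identity
structure that is present with the assumed stability — they say nothing
about how strong that structure is in real recordings.

A caveat worth knowing: per-run drift jitter is itself a per-recording
random "fingerprint". A null cohort intended to show chance-level accuracy
must therefore zero *both* `fingerprint_strength` and `run_drift`; with
drift left on, a classifier legitimately identifies recordings (not
subjects) at far above chance — a session confound, and a useful reminder
of why cross-session evaluation matters.

## Problem sizes and numerical choices

Validation experiments use 10-subject cohorts; chance-level calibration
uses the full 450 s per condition (90 block-averaged trials per subject),
while the multi-seed recovery, drift and band-selectivity experiments use
150 s per (run, condition) — 30 block-averaged trials — which keeps the
multi-cohort suites fast while leaving each accuracy estimate based on
300-900 trials. Five independent seeds are averaged wherever a claim
compares two accuracies.

Other numerics: log floor 1e-12 and Fisher-Z ceiling 1 − 1e-12 (guards
only; transformed values are otherwise exact); coherence clipped to [0, 1];
filters applied with `sosfiltfilt` for zero phase; filter warm-up samples
discarded in the generator; stratified CV fold assignment seeded and
recorded. Degenerate inputs (constant vectors in PCC, single-subject
splits, missing reference channels, double transforms) raise typed errors
rather than returning silent defaults.

## Storage and reproducibility

A single HDF5 store holds `/raw`, `/epochs` and `/features/<kind>`; each
stage group records a hash of the configuration slice that produced it, so
re-running a pipeline with an unchanged config skips recomputation and
reproduces byte-identical report CSVs. EDF recordings are ingested through
MNE's reader with montage and rate validation; synthetic cohorts are stored
directly with a JSON sidecar of the cohort specification.

## Known limitations

* The linear mixing model produces smooth, well-behaved coherence; real
  EEG connectivity features are noisier and more condition-dependent.
* Phase-lag features inherit the generator's zero-lag mixing: synthetic
  phase structure comes only from filtering and noise, so phase-based
  identification is weaker than in real data with true conduction delays.
* Accuracy ceilings (100% intra-run) reflect the generator's clean
  separation at default strength; they are a property of the simulation
  conditions, not a claim about real cohorts.
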