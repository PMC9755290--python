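# Methods

`eegmarkers` is a testbed for a specific question in consciousness
research: when neural oscillations and conscious state come apart, do
spectral EEG features or entropy ("complexity") features generalize
better as biomarkers of wakefulness vs NREM sleep?  Two rare genetic
conditions provide the motivating dissociations: children with Angelman
syndrome (AS) show sleep-like high-amplitude delta EEG while awake, and
children with Dup15q syndrome show wake-like beta activity that persists
into NREM sleep.  The package implements the full analysis chain —
preprocessing, spectral and entropy feature extraction, cross-regime
classifier training/validation, AUC comparison statistics, and a
surrogate-based entropy decomposition — and exercises it end to end on a
synthetic cohort generator that reproduces the essential statistical
structure of those regimes.

## The synthetic cohorts

Real recordings from these cohorts are not freely downloadable, so the
generator (`eegmarkers.synth`) is a first-class component.  Three regimes
are emulated, each as 19-channel 10–20 EEG:

* **AS-like** — dominant 2–4 Hz activity in *both* states (oscillation
  amplitude about 30 µV against a 12 µV 1/f² background, the
  high-amplitude delta phenotype);
* **NT-like** — an 8–15 Hz peak awake, 4–8 Hz dominant asleep;
* **Dup15q-like** — dominant low-beta (16–21 Hz) in both states, in
  3–5 Hz bursts, plus a smaller (0.7 relative amplitude) slow spike-wave
  component so the regime has phase structure at slow timescales too.

Each sleep channel is built as a deterministic nonsinusoidal
oscillation: a frequency-modulated fundamental with Wiener phase noise
(coherence ~0.7 s; ~0.25 s for the Dup15q beta), a per-cycle von-Mises
spike transient (harmonics decay smoothly, no ringing — the temporally
sparse fast content of spike-wave-like activity), and a deterministic
burst envelope, on a pink-noise background.  The wake member of each
pair is a **partial phase-randomized surrogate** of the same per-channel
realization: a fraction `complexity_gap` (default 0.9) of Fourier bins
get fresh uniform phases, independently per channel.  This preserves
every amplitude spectrum exactly (tested to 1e-9 before volume-conduction
mixing) while destroying waveform shape and between-channel dependence —
wakefulness is more temporally disordered at an identical spectrum,
which is the mechanism behind the whole testbed.

Connectivity structure is injected into the template *before* the
surrogate step: a broadband source coupled into designated channel pairs
with symmetric ±lags (24/96/288 ms) has a real cross-spectrum, so it is
invisible to phase-lag connectivity but carries lagged symbolic
dependence; since the wake surrogate destroys it, weighted symbolic
mutual information acquires a spectrum-neutral state signal in every
regime.  A narrowband theta source with one asymmetric lag produces
genuine dwPLI and is active only in the NT-like regime (stronger
asleep); the AS-like and Dup15q-like regimes therefore carry **no**
phase-lag connectivity signal in either state — the spectral-connectivity
dissociation.  Zero-lag mixing (rows of the mixing matrix sum to 1)
emulates volume conduction, and ~5 % of samples are masked in ~1 s
chunks to exercise the validity rules.

Choices worth knowing about:

* Per-channel fundamental-frequency jitter (±6 %, ±15 % for the Dup15q
  beta) and phase diffusion exist because *deterministic* equal-frequency
  channels remain pattern-aligned within a 5-s analysis window, which
  inflates symbolic-MI estimates between genuinely uncoupled channels;
  physiological rhythms have finite coherence, and modelling that removes
  the artifact.
* Fundamentals are drawn from the central 60 % of each dominant band so
  every participant's spectral peak sits inside the band.
* The direction of the wake−sleep wSMI difference in the testbed is
  sleep-high at slow delays and wake-high at fast delays; what the
  classifiers rely on is that the *pattern* is consistent across regimes,
  not its sign at any one delay.
* The wake−sleep PermEn difference at τ = 8 ms (one sample at 125 Hz)
  is near zero or slightly negative in slow-wave regimes: at lag one,
  the surrogate's Rayleigh-enveloped fast content produces fewer
  micro-reversals than the original's constant-amplitude harmonic
  wiggle.  The strictly-positive wake gap is guaranteed (and tested) for
  mMSE, LZ76, CTW and PermEn at delays of two samples and up.
* Masks stand in for artifacts; no attempt is made to simulate
  epileptiform discharges, blinks, or EMG.

## Preprocessing

45 Hz linear-phase FIR lowpass (order = 2 × sampling rate,
Hamming-windowed, applied centered, i.e. zero phase) followed by a
0.4 Hz 5th-order Butterworth highpass (forward–backward by default;
single-pass available).  The analog prototype of that highpass
attenuates 0.5 Hz by 0.443 dB — one of the two analytic constants the
package pins down.  Recordings are then average-referenced.  Validity:
a recording is sufficient when at least 15 windows of 10.9 s (the 0.5 Hz
wavelet window), hopping at 25 % of the window, contain ≥ 80 % usable
samples; the analytic minimum usable duration is
0.8 × (10.9 + 14 × 2.725) = 39.2 s.

## Features (42 per recording-state)

* **scSpectralA/R** — 7-cycle complex Morlet PSD at 49 log-spaced
  frequencies (8/octave, 0.5–32 Hz; kernels truncated at ±2.5 SD, unit
  energy; windows = kernel support, 75 % overlap, ≥ 80 % usable),
  integrated (trapezoid) into six octave bands with inclusive lower and
  exclusive upper bounds; relative powers sum to 1.  Channel-averaged.
* **fcSpectral** — debiased WPLI-square from cross-spectral densities
  estimated by Hamming-tapered direct DFTs at the wavelet frequencies in
  2-s segments (50 % overlap) inside 5-s windows; windows are the
  observations.  Averaged within bands and over short-range (80–130 mm)
  and long-range (≥ 130 mm) channel pairs of a fixed adult 10–20
  template; pairs under 80 mm are excluded.
* **scEntropy** — PermEn (m = 3, τ ∈ {8, 16, 32, 64, 128} ms at 125 Hz,
  5-s windows with 50 % overlap, ties broken by temporal order,
  normalized by ln 6); mMSE (fuzzy sample entropy with sigmoidal
  membership μ(d) = 1/(1+exp((d−0.5)/r)), m = 2, r = 0.15 in units of
  each timescale's SD — the coarse-grained series is re-standardized per
  scale, which is what "dynamically updated radius" means here — 30-s
  segments, scales 1–20 computed, 1–10 averaged, ≥ 100 valid coarse
  samples per scale); LZ76 (median-binarized, exhaustive 1976 parsing,
  normalized by N/log2 N, 60-s segments, ≥ 2000 usable samples); CTW
  entropy rate (binary context-tree weighting, depth 20,
  Krichevsky–Trofimov node estimators, zero-padded initial context).
* **fcEntropy** — wSMI per channel pair: joint ordinal-pattern
  distributions per 5-s window, identical and sign-opposite pattern
  pairs zero-weighted, natural-log MI normalized by
  2/(PE(X)+PE(Y)) with *unnormalized* local permutation entropies (so
  numerator and denominator share units), averaged over short/long-range
  pairs.

Note the dynamic mMSE radius makes white-noise entropy flat across
scales by construction (the classic variance-driven decline is exactly
what it corrects away); the estimator's signature is tested as flat-high
for white noise and lower for autocorrelated signals.

## Selection and classification

Features are pooled across cohorts and z-scored (n−1 convention), as in
the source design — validation rows influence standardization but never
selection or hyperparameters (regression-tested).  Two selection paths:

* **LMM** — per feature, a REML linear mixed model of the z-scored
  feature on state (wake = 0, NREM = 1) with participant random
  intercepts; |β| > 0.5, strictly.  Singular fits fall back to the
  paired-difference mean (flagged).
* **PCA** — per category, PCA of participant-level wake−sleep contrast
  vectors, keeping the fewest components reaching 90 % cumulative
  explained contrast energy.  The contrast vectors are **not**
  mean-centered by default: with centering, when the mean contrast is
  large relative to its between-participant variability (as in this
  testbed), the top components describe only participant idiosyncrasies
  orthogonal to the effect and the downstream classifier fails to
  transfer; the uncentered second-moment PCA keeps the mean contrast in
  the leading component.  `center=True` restores the covariance variant.

Classification is L1-regularized logistic regression (wake positive;
the 100-point log grid λ ∈ [4.4e-5, 0.44] maps to scikit-learn's
C = 1/(λ n)); λ minimizes grouped 10-fold cross-validated deviance with
a participant's two rows always on the same fold side.  Operating-point
metrics (accuracy, precision, recall, specificity) are taken at the
Youden-J maximum of the ROC curve — a documented convention choice.
AUC uncertainty uses a participant-paired BCa bootstrap (both state rows
resampled together; degenerate single-class resamples are redrawn and
counted).  AUCs convert to z-scores via U = AUC·N²; the default variance
N²(N²+1)/12 follows the printed formula this pipeline reproduces, and the
classical Mann–Whitney null variance N²(2N+1)/12 is available — the two
differ substantially, the printed form being far more conservative, and
only the classical form tracks the exact permutation tail within a
factor of 2 at small N (this discrepancy is surfaced, not silently
corrected).  The z-difference z′ = (z₁−z₂)/√(1/(N₁−3)+1/(N₂−3)) compares
entropy vs spectral AUCs (valid as a test for N₁ = N₂); p-values are
Benjamini–Hochberg corrected across the comparison family.

## Entropy decomposition

For matched sets of 5-s segments per state, the observed
ΔPermEn = PermEn(wake) − PermEn(sleep) is split into three additive
terms using phase-randomized and phase-swapped surrogates.  Writing
G(X, Y) for the surrogate-mean PermEn of signals with amplitude spectra
drawn from condition X and phases from condition Y (Y = "rand" meaning
i.i.d. uniform phases; one random donor segment per surrogate):

    amplitude   = G(w, rand) − G(s, rand)
    phase       = ½[(G(w,w) − G(w,s)) + (G(s,w) − G(s,s))]
    interaction = Δtotal − amplitude − phase        (exact residual)
    non-amplitude = phase + interaction

Amplitude-only contrasts (phase-random noise differing only in spectrum)
put ≥ 90 % of the total in the amplitude term; phase-only contrasts
(identical spectra, different phase structure) leave the amplitude term
within Monte-Carlo uncertainty of zero — both are tested as ground
truths.  Per-participant, per-τ components are compared
(amplitude vs non-amplitude) with a mixed model with participant random
intercepts, BH-corrected over τ, with a paired Cohen's d
(mean difference / SD of participant-level differences, a within-subject
convention).

## Problem sizes and the reduced profile

The default study conditions are 3 regimes × 10 participants × 2 states
at 120 s per state and 125 Hz (all symbolic measures run natively at
125 Hz; the τ grid stays integer there).  The `reduced` feature profile
used for the testbed runs computes mMSE on one channel (Cz, first 30-s
segment, scales 1–10), LZ76/CTW on five spread channels, and
connectivity on a random-but-fixed subsample of 18 short and 18 long
pairs; single-channel EEG measures have low spatial variability, so
subset means estimate the all-channel mean well, and the subsampled pair
classes remain unbiased estimates of the class means.  The `full`
profile computes everything on all channels and pairs.  Acceptance-style
runs (10 replicates of the full pipeline) recover the headline result —
entropy classifiers ≥ 0.9 AUC on both validation regimes, spectral
connectivity ≤ 0.7 on the dissociated regime, entropy-vs-spectral
comparison significant at q = 0.05 — in ≥ 8 of 10 seeds.

## Numerical and degenerate-input conventions

* dwPLI returns exactly 0 when the summed |imaginary cross-spectrum| is
  below 1e-9 of the summed |cross-spectrum| (zero-lag or identical
  channels), rather than roundoff noise; values in the 0.5–1 Hz band are
  estimated below the 2-s segment resolution and have a wider null
  spread than the resolvable bands.
* Features with no valid windows/segments are missing (NaN), never zero;
  zero-variance columns abort pooled z-scoring with the column name.
* Constant signals yield NaN mMSE (zero SD); wSMI is NaN when both
  windows have zero local permutation entropy.
* The λ-grid classifier fit is deterministic given a seed (fold
  assignment and the liblinear solver are both seeded).
* An |β| threshold comparison uses a 1e-9 guard so a coefficient landing
  exactly on 0.5 is not selected (strict inequality).

## Known limitations

The generator reproduces the *statistical* structure the analysis needs
(matched spectra with an entropy gap, regime-specific bands,
dissociated connectivity), not the morphology of real clinical EEG: no
eye blinks, EMG, electrode pops, epileptiform discharges, sleep
spindles/K-complexes, or nonstationary arousal structure.  Passing tests
therefore show the *pipeline* behaves as designed under the stated
dissociation, not that any specific clinical dataset would yield the
same AUCs.  Real-data tables from the motivating study (which require
restricted clinical EEG) are out of scope, as are ICA artifact removal,
channel interpolation, spindle detection, and full spectral
parameterization (a simplified log-log-residual peak picker stands in).
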