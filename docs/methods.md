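# Methods

This note documents the models, parameter choices and numerical conventions
behind `korosound`, the design decisions taken where the method left room,
and what validation on synthetic records does and does not establish.

## Signal model and working rate

A Korotkoff-sound (KS) recording is modeled as `y(n) = s(n) + d(n)`: a train
of 10–40 short (< 150 ms) damped-oscillation pulses `s(n)` with energy
concentrated in 50–400 Hz, embedded in broadband measurement noise `d(n)`,
with silent stretches before the first and after the last pulse (cuff
pressure above systolic / below diastolic).

All analysis runs at a **working rate of 800 Hz**. This is the unique rate at
which a 3-level wavelet-packet tree produces leaves of exactly 50 Hz width
(0–50, 50–100, …, 350–400 Hz), i.e. precisely the band grid on which the
energy features are defined. Input audio of any rate is polyphase-FIR
resampled (anti-aliased) on load, and records are peak-normalized to
`max|x| = 1`, which — together with the ratio/normalized form of every
feature — makes the entire 46-feature vector invariant to recording gain
(asserted by test).

## Wiener denoising

The minimum-mean-square-error criterion is realized as a short-time spectral
Wiener filter: Hann-windowed 40 ms frames with 50 % overlap, per-bin gain
`G = ξ/(1+ξ)` with the a-priori SNR ξ tracked by the decision-directed rule
(smoothing 0.98) and a gain floor of 0.05. The noise spectrum is the average
periodogram of the first 0.5 s of the recording — the silent lead-in of a
cuff measurement carries only noise — and is overridable. Bins with zero
estimated noise get unit gain, so a zero noise profile is an exact identity;
gains never exceed 1, so denoising never increases signal energy.

## Shannon envelope and segmentation

Per 40 ms frame (50 % overlap) the Shannon energy
`E_j = −(1/N) Σ z_i² ln z_i²` is computed with `z` the record scaled by its
**global** peak. Scaling by the *frame* maximum instead would rescale every
frame to peak 1 and make the envelope blind to pulse amplitude; record-level
normalization follows the established Shannon-envelope segmentation
literature and keeps envelope peaks proportional to pulse salience. The
envelope is standardized to mean 0 / std 1 (population standard deviation,
which makes the two-point case `{0, 2} → {−1, +1}` exact).

Anchor location and clean-up:

* local maxima with `P ≥ 0.2·max(P)` *and* `P > 0` become anchors (the
  positivity guard keeps the relative threshold well-posed on a zero-mean
  series);
* anchors closer than 100 ms are merged greedily left-to-right; within a
  cluster the tallest envelope value survives (the most salient pulse);
* artifact rejection is quantified as: the KS train is the longest run of
  consecutive anchors whose gaps lie in [0.3 s, 2.0 s] (heart rates of
  30–200 bpm); anchors farther than 2.0 s from that run are friction clicks
  and are dropped. Fewer than 3 anchors skip the rule with a warning;
* the record span is `B = max(0, first − 0.3 s)`, `E = min(T, last + 0.5 s)`,
  i.e. the 300/500 ms searches extend the span symmetrically outwards from
  the train's ends; per-beat analysis windows are `[anchor − 0.1 s,
  anchor + 0.3 s]`.

## Features

**Wavelet packets.** The per-band energies come from a 3-level wavelet-packet
decomposition with periodized boundary handling, leaves reordered from tree
order to natural frequency order (a classic correctness trap: for wavelet
packets the two orders differ). The default wavelet is **db24**. Orthogonality
is required for exact energy conservation (Parseval error at machine
precision; signals are trimmed to a multiple of 8 samples, ≤ 7 samples, to
keep the periodized transform square). Among orthogonal choices the filter
must also be sharp enough that a tone at a band center leaks little into the
neighbouring 50 Hz band: db8 leaks up to 22 % of such a tone's energy, db24
at most 8.7 %, which keeps wavelet band shares within 10 points of an FFT
band-energy oracle. The near-brick-wall discrete Meyer filter would leak only
5 % but is not exactly orthogonal (≈ 0.7 % energy error), so it was rejected.

**Energy block (19).** The seven global ratios `S_total(j)` are renormalized
to sum to exactly 1 and reported in percent. Per beat, `en` is the 50–100 Hz
fraction and `en_h` the 150–400 Hz fraction of the beat's 50–400 Hz energy
`Et`; the 100–150 Hz band belongs to neither ratio, so `en + mid + en_h = 1`.
Scale conventions reconcile the two families of summaries: `en`/`en_h`
statistics (std, max, min) are the raw fractions ×100 (so `enr_max ≤ 100`),
while `Et` and the inter-beat interval `Ti` are first mean-normalized
(`Ep = Et/mean(Et)`, `TM = Ti/mean(Ti)`, each series has mean exactly 1) and
then ×100 (so `TM_max` sits near 100 and a perfectly regular train gives
`TM_max = TM_min = 100`). Population standard deviations throughout.

**Statistical block (12).** Mean, median, std, mean absolute deviation,
quartiles (linear interpolation), IQR, skewness (standardized third moment),
kurtosis (Pearson: normal → 3) of the amplitude samples over `[B, E]`;
dominant frequency as the periodogram argmax restricted to 50–400 Hz, with
its peak power and the peak's share of in-band power. A constant signal sets
skewness/kurtosis to 0 with a warning.

**Entropy block (2).** Shannon entropy (base 2) of a 128-bin amplitude
histogram and of the periodogram normalized to a probability distribution;
empty bins contribute 0. Bin count is configurable and recorded in the
extraction metadata.

**MFCC block (13).** 40 ms / 50 % frames, spectra zero-padded to a 256-point
FFT so the narrow low-frequency Mel triangles are resolved at 800 Hz; 26
triangular filters equally spaced on the Mel scale over 0–400 Hz; filter
energies floored at 1e−10 of the frame maximum before the log (a *relative*
floor, so gain invariance is exact); DCT
`c(n1) = Σ_m log E(m) · cos((m−0.5)/M · n1 · π)` for orders 1–13, averaged
across frames. Because the order ≥ 1 cosines sum to zero over m, a constant
log-energy offset — i.e. any waveform gain — cancels exactly.

Of the mentions of 46/47/48 features in different accounts of this feature
family, the enumerated groups (19 + 12 + 2 + 13 = 46) are what the package
computes. Statistical/entropy/MFCC features are computed once over the whole
`[B, E]` span (not per beat); feature sets are A = energy+statistical+entropy
(33), B = statistical+entropy+MFCC (27), C = all 46.

## Classification

Stratified 80/20 split; per-feature min–max scaling fitted on training rows
only (constant columns map to 0 with a warning; test values are deliberately
not clipped); stratified 10-fold cross-validation on the training split with
scaling refit inside each fold. CHF is the positive class, so sensitivity is
the patient detection rate. F1 is the harmonic mean of sensitivity and
precision by definition; when Se = Ps = 0 it is set to 0 by convention.

**BO-SVM.** The surrogate is a Gaussian process (Matérn 5/2 + white noise,
normalized targets) over `log10 c ∈ [−3, 3]` and `log10 g ∈ [−4, 1]`;
acquisition is expected improvement (ξ = 0.01) maximized over 1024 uniform
candidate points per iteration; 5 random initial evaluations, 30 evaluations
total by default. The objective is 10-fold CV accuracy of an RBF SVM on the
scaled training split. The whole trajectory is deterministic given the seed
and is stored in the trained model.

**Baseline presets** (names → parameters, recorded in model metadata):
decision trees with at most 100/20/4 splits (fine/medium/coarse); KNN with
k = 1 Euclidean (fine), k = 10 Euclidean (medium), k = 10 cosine, ties broken
by the nearest neighbour's class; Gaussian Naive Bayes and a kernel-density
Naive Bayes (per-class, per-feature Gaussian KDE with Silverman bandwidth);
30-learner ensembles — AdaBoost on depth-1 stumps, bootstrap-aggregated
trees, and RUSBoost (per-round class-balanced undersampling, weak learner a
depth-1 stump, AdaBoost reweighting on the full set). RUSBoost and the
kernel NB are implemented in-package.

Serialized models (CLI) store family, hyperparameters, scaler and a reference
to the training feature table plus seed; evaluation refits deterministically
from that reference rather than serializing kernel support vectors.

## Synthetic records

The generator emulates the signal statistics of a cuff measurement, not the
hemodynamics: each beat is a sum of exponentially damped sinusoids
(components given as center frequency, bandwidth — the Lorentzian half-power
width `1/(π τ)` — and relative amplitude), Gaussian-windowed below 150 ms;
beat times are a jittered renewal process (default period 0.8 s ± 0.06 s);
pulse amplitudes rise then fall across the train; white Gaussian noise is
added at a target SNR (default 20 dB, defined against the pulse-train power);
Poisson-count friction clicks land in the silent phases. Ground-truth beat
times mark each pulse's *amplitude peak* (what an envelope anchor estimates);
under zero jitter their successive differences equal the period exactly.

Clicks are placed uniformly over the *outer* silent phases, keeping a 2.2 s
guard to the beat train and staying clear of the first 0.5 s noise-estimation
window. Friction artifacts in practice cluster at the very start and end of a
recording (handling of cuff and stethoscope), and the guard is what makes the
isolation-based rejection rule (> 2.0 s) able to act at all — a click glued
to the train is indistinguishable from an early/late beat without extra
morphological modeling, which is out of scope.

The two cohort templates encode the direction of the Valsalva observations:
the reduced-output template shifts pulse energy from 100–200 Hz toward
50–100 Hz and above 200 Hz and shrinks the beat-to-beat spread of the energy
ratios (`en_jitter` 0.25 → 0.08). Cohort generation jitters all spec
parameters by ±10 % per record for within-class variance; identical templates
for both labels give a null cohort. All randomness flows from one seed.

What passing synthetic tests shows: the chain recovers programmed beat times,
band shares and variability levels, separates programmed contrasts, and finds
no signal where none was programmed. What it does not show: performance on
clinical recordings — real KS has nonstationary noise, cuff-pressure-dependent
pulse morphology, murmur overlap and subject-level covariates that the
generator does not emulate.

## Problem sizes and tolerances

The validation suite uses 50 + 50 contrast records and 100 + 100 null records
(≈ 22 beats each), 50 ground-truthed records at 15 dB SNR for anchor
recovery (±50 ms matching), 30 seeded trials for artifact rejection, and
30-evaluation BO runs — sizes chosen so the whole suite completes in about a
minute while keeping binomial noise on reported rates small. Key tolerances:
Parseval ≤ 1e−6 relative (achieved: machine precision), envelope
standardization ≤ 1e−9, brute-force oracle agreement ≤ 1e−9, WP-vs-FFT band
shares ≤ 10 points, anchor recall/precision ≥ 0.95, feature gain invariance
≤ 1e−6 relative.

## Known limitations

* The Wiener filter assumes the lead-in is noise-only; a recording that
  starts mid-train will whiten its own signal (the lead-in length is
  configurable for such cases).
* Band features assume the 800 Hz working grid; content above 400 Hz is
  discarded by design.
* The per-beat `en`/`en_h` ratios are undefined for beats with no 50–400 Hz
  energy; such beats are skipped with a warning.
* The artifact-rejection rule cannot remove clicks that fall within 2 s of
  the pulse train, and a recording with fewer than 3 detected pulses skips
  rejection entirely.
* Kernel-NB inference is O(n_train · n_test · n_features) — fine at study
  scale, slow for thousands of records.
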