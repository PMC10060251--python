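# Methods

## Signal model and preprocessing

A recording is a channels × samples block in microvolts with a sampling rate
and unique channel labels.  The conditioning chain is:

1. **Broadband filter.**  A linear-phase least-squares FIR band-pass,
   0.5–70 Hz, with a 50 Hz notch carved into the same design (stop band
   49.5–50.5 Hz, transition 1 Hz, least-squares weight 50).  The order scales
   with the rate, 4.8 taps per Hz (4800 at 1000 Hz), rounded to even so the
   filter is symmetric; applying it with the centre tap aligned to each
   sample makes the output time-aligned with the input.  The designed
   response is flat to <0.1% across 1–69 Hz and >100 dB down at 50 Hz.
2. **Bad channels.**  A channel is flagged when the robust z-score of its
   log variance exceeds 3 — the scale is 1.4826·MAD floored at 0.05
   log-units, because with near-identical channels the MAD collapses and
   would flag numerical dust — or when its maximum absolute correlation with
   every other channel falls below min(0.4, half the median of the
   per-channel maxima).  The relative gate makes the correlation rule fire
   only in recordings that are globally correlated (as scalp EEG is); in a
   mutually uncorrelated recording it stays silent.  At most 25% of channels
   are flagged (worst offenders kept, with a warning).  In cohort runs a
   channel is excluded for everyone when it is flagged in ≥25% of subjects:
   profiles must share one feature space, and sporadic single-subject flags
   at synthetic SNRs are statistical rather than hardware events.
3. **Common average reference.**  The per-sample mean over good channels is
   subtracted from every channel; idempotent, and bad channels never enter
   the average.
4. **Band decomposition.**  Order-4 Butterworth band-passes applied
   forward–backward (zero phase, effective order 8) for δ 1–4, θ 4–8,
   α1 8–10, α2 10–13, β 13–30 Hz.

Processing is whole-recording; no epoching.

## PLI, crossings, TBPC

Instantaneous phase comes from the analytic signal (Hilbert transform, no
padding).  For a pair, Δφ(t) is the wrapped phase difference and
s(t) = sign(sin Δφ(t)).  PLI = |Σ s(t)|/T uses raw signs (zeros count 0, so
identical signals score exactly 0).  For crossings, exact zeros of s(t) are
carried over from the last nonzero sign (leading zeros take the first
nonzero), keeping the episode partition exhaustive; an all-zero series is
degenerate.  A crossing sits at the midpoint of the two samples of a sign
change — no sub-sample interpolation, since the sign series is the defined
intermediate object.  In implementation the sign of sin Δφ is read off the
imaginary part of z_i · conj(z_k), which is proportional and avoids angle
computations.

The triplet map assigns every unordered pair (i, j) the good electrode k
minimising the Euclidean distance in 3-D sensor space to the pair midpoint
(exact ties go to the lexicographically smallest label).  The TBPC
coefficient of (i, j) matches each crossing of connection (i, k) to its
nearest crossing of (k, j) and vice versa, sums the absolute lags, halves
the sum and divides by the duration: units ms/s, symmetric in the two
trains, 0 for identical trains, 0 (flagged degenerate) if either train is
empty.  A "next-following-crossing" matching rule is available behind a
config enum; nearest matching is the default because it is symmetric and
parameter-free.  How lags are matched and normalised is a design choice of
this package: the coefficient's defining text leaves the pairing rule and
the time unit open, and alternatives (signed lags, per-minute units) would
scale but not reorder the profiles.

Pair indices are canonical (labels sorted), and profiles list pairs in
lexicographic order, so shuffling input channel order changes nothing
downstream.  Note the coefficient's magnitude *decreases* as trains densify
(nearest neighbours get closer) and grows when sparse trains are mismatched;
it is near zero only when the two connections cross at nearly the same
times — e.g. when the common electrode's phase slips drive both.

## CPM

Features are the band-major flattened profile.  Per training fold:
Welch t-tests (group outcome) or Spearman tests (continuous outcome) per
feature; selection at p < threshold split by effect direction into positive
and negative sets; z-scoring by training mean/SD (zero-SD features are
dropped from the masks); network strengths = mean of z-scored selected
features per (band, direction), exactly 2 × n_bands predictors with empty
masks contributing 0 so the design never changes shape; then a logistic
(P_PD) or ordinary least-squares (score) regression.  Constant predictor
columns are excluded from the fit and given weight 0.  A logistic fit that
(quasi-)separates falls back to a ridge-penalised fit (L2, C = 1) and is
flagged.  Predictors can be restricted to a named subset
(e.g. `theta_neg, delta_pos, beta_pos`).

LOOCV repeats all of the above without the held-out subject, per threshold
in the grid {0.0001, 0.001, 0.005, 0.01, 0.05}, and averages the held-out
scores over thresholds.  Two leave-one-out artifacts are handled explicitly:

* a logistic fold with no informative predictor predicts 0.5, not the
  training base rate — in LOOCV the training prevalence is deterministically
  anti-correlated with the held-out label (its mean is 0.5 − y/(2n)), which
  would pin null AUC to exactly 0 at strict thresholds;
* thresholds at which *every* fold is intercept-only are dropped from the
  threshold average — an intercept-only linear fold predicts the training
  mean, which is exactly anti-monotone in the held-out outcome (per-threshold
  Spearman −1).

Folds that do have live predictors keep their standard intercept, so the
familiar conservative bias of leave-one-out correlation evaluation remains:
held-out r slightly *under*-states true association, and on pure noise the
held-out AUC sits at or slightly below 0.5 (training-fold selections
anti-match the held-out subject).  Permutation checks in the test suite are
therefore one-sided where sample sizes are small: genuine leakage would show
up as excess *above* chance.

AUC is pairwise concordance with ties counted ½ (verified exactly against
exhaustive pair counting); Spearman uses average ranks and a Fisher-z 95% CI
with SE = 1/√(n−3).  At r = −0.41, n = 54 the interval is [−0.61, −0.16].

## Synthetic cohorts

Channels are sums of per-band unit-RMS narrowband Gaussian oscillators
(order-4 Butterworth-filtered white noise, 2 s burn-in) scaled by a coarse
resting spectrum (δ 8, θ 7, α1 6, α2 5, β 4 µV RMS) plus 5 µV white noise.
A coupling edge makes two channels share one oscillator: the analytic signal
is rotated by ±lag/2 on the two channels, and a Poisson process of rate
`switch_rate` flips the lag sign — manufacturing phase crossings at a
controllable rate.  Per channel and band the mixture is normalised so band
power is independent of how many edges the channel joins.  The montage is a
Fibonacci spiral on a spherical cap (radius 9 cm).

Cohort defaults (the study conditions for all calibration results):
baseline coupling is a greedy nearest-neighbour matching per band — one
partner per channel, strengths U(0.8, 0.95), lags U(0.5, 1.3) rad of random
sign, base switch rate 0.5 Hz.  Three of these choices are load-bearing and
were set during generator development: a channel's band power must not be
split over many edges (each edge needs a ≥⅔ power share for its dynamics to
survive into the measured phase), coupled pairs must be *short* (the triplet
map only ever uses near-midpoint pairs as connections, so long coupled pairs
are invisible to the profile), and the base switch rate must sit in the
responsive part of the crossing-rate curve (the measured rate tracks the
switch rate ~1:1 up to ~2 Hz and saturates near the band width).  Short-range
dominant-partner coupling is also the physiologically sensible idealisation
for scalp EEG.

The group effect adds `effect_size` (default +2 Hz switch rate; alternatively
a coupling-strength shift) on a fixed random 5% of pairs in the effect band
(θ), scaled per PD subject by a latent severity ~ U(0.7, 1.3); the follow-up
score is 29 − 3·severity + N(0, 1), clipped to [0, 30]; controls have
severity 0 and no follow-up score.

What the generator does *not* emulate: 1/f background, volume-conduction
forward models, artifacts (blinks, muscle), realistic topographies, or
non-stationary band power.  Passing calibration therefore shows the
*pipeline* is correct and unbiased, not that real PD EEG is this separable.

## Calibration results the tests compute

* Null cohorts (no planted effect, 20 seeds at 16 channels / 60 s / 250 Hz /
  20+20 subjects): median LOOCV AUC within 0.5 ± 0.1 (measured ≈ 0.46; the
  small deficit is the conservative LOOCV bias above).
* Planted θ effect at the same scale: median LOOCV AUC ≥ 0.9 and > 80% of
  features selected at p < 0.01 lie in θ.
* Crossing-rate control: measured crossings/s is strictly increasing in the
  switch rate over {0.5, 1, 2, 4} Hz.

The continuous-outcome arm is intrinsically harder at desk scale: the
within-PD severity gradient moves features by less than their 60-s
measurement noise when only ~6 pairs carry the effect, and a switch-rate
effect saturates (see above), so outcome-linked demonstrations use the
coupling-loss mechanism (`effect_on="strength"`, smooth dose-response) with
a diffuse effect (20% of pairs), widened severity U(0.3, 1.7), outcome noise
0.5, and n = 54 patients; there the held-out Spearman r is stably weak
positive (~0.1–0.3).  At 20 patients the same quantity has seed-to-seed
spread of ±0.4 around zero and is not a meaningful summary.

## Numerical and interface notes

* EDF files are written by a built-in plain-EDF writer (16-bit, 1-s records,
  per-channel physical scaling; integer sampling rates only) and read via
  mne; expect 16-bit quantisation on round-trip.  The text matrix format
  (`fs=` header + one whitespace row per channel) round-trips exactly, as do
  all TSV artifacts (floats written with 17 significant digits and parsed
  in round-trip mode).
* Profile caching keys on a content hash of the raw recording, the pooled
  bad-channel set and the profile-relevant configuration; the run-level
  provenance hash excludes file paths, so identical analyses hash identically
  wherever the files live.
* Determinism: cohorts derive all per-subject seeds from one seed via
  `SeedSequence.spawn`; identical config + seed reproduces every output
  byte-for-byte.
* Degenerate inputs: constant signals have no phase and are rejected;
  identical channels give a degenerate sign series, and their TBPC is 0 with
  the (band, pair) recorded; folds whose training split loses a class are
  aborted and reported.
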