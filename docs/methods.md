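# Methods

`sefpredict` implements a complete, testable analysis chain for predicting
antidepressant treatment response from pre-treatment resting-state EEG:
transient spectral event features (SEF) and averaged power features (APF)
from the frontal 10–20 montage feed an elastic-net regression of the
percentage change in depression score, followed by channel-level biomarker
statistics. Because the motivating clinical dataset is access-controlled,
the package ships a ground-truthed synthetic cohort generator; every claim
the test suite makes is a claim about recovering structure that the
generator planted.

## Signal model and synthetic data

A synthetic recording is `background + bursts`, per channel, in µV.

**Bursts.** A burst is a Hann-tapered sinusoid of `n_cycles` cycles at a
band's center frequency (delta/theta 2–5 Hz, alpha 6–14 Hz, beta
15–29 Hz), injected at Poisson-distributed onsets (`rate_per_epoch` per 5 s
epoch), with lognormal amplitude (default coefficient of variation 0.15)
and uniform phase. The Hann taper concentrates the burst into a compact
time-frequency blob without committing to the analysis wavelet.

**Background.** The background is a bank of log-spaced constant-amplitude
oscillators (spacing ≈ f/4.5, i.e. 2–3 oscillators per Morlet bandwidth at
every analysis frequency, 0.7–55 Hz) whose instantaneous frequencies drift
slowly (Ornstein–Uhlenbeck, relative sd 2%, time constant 0.5 s), with
amplitudes shaped so the PSD falls off as 1/f^χ (default χ=1). This
construction is deliberate and load-bearing: the narrowband power of a sum
of a few constant-modulus phasors has bounded tails, so the background
essentially never crosses the 6× factor-of-median event threshold (measured
maximum FOM ≈ 4–5.5; zero spurious event maxima in 100 epochs in all three
bands). A Gaussian 1/f background cannot play this role — for *any*
Gaussian process the Morlet power envelope is exponentially distributed and
spends exactly 2⁻⁶ ≈ 1.6% of the time-frequency area above 6× its median,
which at these bandwidths produces ≈ 0.8 spurious beta maxima per second
per channel and makes "planted-event recovery" ill-posed. Real resting EEG
does produce events at that rate at this threshold; the package's position
is that a *ground-truth* generator must have an event-free background by
construction, and that this is the main feature of real data the generator
intentionally does not emulate. Consequences: recovery and false-alarm
results on synthetic data do not bound false-alarm behavior on real
recordings, where the 6× threshold is a definition of "event", not a
detector of planted ones.

Channels share a common background component (default 90% of variance,
with ±5% per-channel gain jitter), emulating volume conduction: raw
inter-channel correlations land near 0.9, which keeps the default
bad-channel criterion (windowed correlation < 0.8) from firing on clean
data, and which the common average reference later removes almost exactly.

**Cohorts.** Each subject draws per-band burst parameters (center
frequency, rate, amplitude, and a subject-level `n_cycles` with ±1-cycle
per-channel jitter) from truncated normal distributions. Burst amplitudes
default to 14.5/9/8 µV (delta-theta/alpha/beta), calibrated once so that
planted events read out near peak FOM ≈ 10 *after* the standard pipeline
(the common average reference removes the shared background, which lowers
the per-frequency median and raises FOM). The outcome is built from the
true planted features: the standardized true value of each weighted feature
(default: `Fp1_beta_duration` with weight −1) forms a latent predictor that
is mapped affinely onto a %change scale with mean −40 and total sd 25
(clipped to [−100, +50]); `outcome_noise_sd` (default 20) is the residual
sd, so the default planted effect explains 1 − (20/25)² = 36% of outcome
variance. Post-treatment HAM-D is the rounded integer implied by baseline
(truncated normal, mean 18.5, sd 3.5, ≥ 14) and %change; the analyzed
%change is recomputed from the rounded scores so responder (≤ −50%) and
remitter (post ≤ 7) flags are exactly consistent. Placebo-like cohorts
have no weighted features and residual sd 25. Cohort sizes default to the
trial's arms (82 treated, 94 placebo); per-subject recordings default to
150 s (30 epochs) at 200 Hz — a deliberately desk-scale stand-in for the
~355 s recordings the channel-level statistics were designed around, chosen
because 30 epochs already give ≈ 45 beta events per channel and a
detected-vs-planted duration correlation near 0.9.

A sign convention worth stating: with a negative weight on duration, the
synthetic correlation between duration and signed %change is negative, so
*improved* subjects (very negative %change) have *longer* planted
durations. The post-hoc responder/remitter contrast therefore takes its
one-sided direction from the observed correlation sign instead of
hard-coding a direction.

`generate_feature_cohort` is a fast path that emits the per-subject SEF
table directly from the true parameters (plus 5% relative measurement
noise), skipping EEG rendering and detection. It is used for
modeling-level calibration studies (type-I error of the permutation test)
where the detection stage is irrelevant.

## Preprocessing

Zero-phase FIR band-pass (Hamming window, via MNE's filter design) at
0.5–50 Hz; bad channels flagged when the median across 5 s windows of
their maximum absolute correlation with any other channel falls below 0.8,
or when they are flat (1 s sd < 0.1 µV) for ≥ 5 contiguous seconds, and
removed without interpolation; 1 s windows (non-overlapping, aligned to
t=0) removed when any channel's RMS or kurtosis z-score across windows
exceeds 5; common average reference; segmentation into 5 s epochs of the
frontal channels Fp1, Fpz, Fp2, Fz, F4, F3, F7, F8 (trailing remainder
dropped). The numeric thresholds are conventional cleaning defaults — the
procedure names the criteria but not values — and all are exposed in the
config. The report records removed windows and the original start times
of kept ones, so planted-event times can be mapped onto the cleaned time
axis (`PreprocessReport.map_times`); with a single outlier among n windows
the attainable z-score is (n−1)/√n, so the z=5 criterion needs ≥ 27
windows to fire at all. Independent-components ocular cleanup is out of
scope: the synthetic data has no ocular artifacts, and externally cleaned
recordings can enter at any stage boundary.

## Spectral events

Morlet wavelet power (7 cycles at every frequency, unit-energy wavelet,
support ±4σ capped at the epoch length) on a 1 Hz grid from 1–30 Hz, per
epoch. Power at each frequency is divided by its median across *all*
epochs and samples of the channel ("factor of median", FOM) — making every
event quantity invariant to global rescaling of the signal, and the
per-frequency median of the normalized map exactly 1. Events are local
maxima of the FOM map that reach 6× median, with multiple events allowed
per connected suprathreshold region. A grid point is a maximum when it
beats all 8 neighbors — strictly, or with equality while earlier in
(time, then frequency) scan order, so exact-tie plateaus resolve to one
deterministic representative. Candidate peaks are restricted to band rows
and to samples further than half a wavelet support from the epoch edges
(capped at 40% of the epoch per side; at 2 Hz the mask is large and
low-frequency rates are correspondingly conservative). Each event's
duration is the full width at half the peak's FOM along time at the peak
frequency, and its frequency span the analogous width along frequency at
the peak time, both with linear interpolation at the half crossings;
widths cut off by an epoch or grid boundary are measured to the boundary
and flagged censored (censored widths stay in the means). Note the
duration of a planted Hann burst reads out as the FWHM of its *power*
envelope (≈ 0.36× the tapered length) convolved with the wavelet's own
FWHM (≈ 0.09 s at 20 Hz) — a monotone mapping of the planted `n_cycles`,
which is what the recovery and ordering tests rely on.

SEF aggregation per (channel, band): event rate per 5 s epoch and
unweighted means of duration, span, and peak FOM power; cells with no
events get rate 0 and NaN means (left to imputation).

The threshold-calibration procedure correlates, across epochs, the raw
power summed over the suprathreshold area {FOM ≥ cutoff} of a band with
the epoch's mean band power, at cutoffs 2, 4, 6. Raw power (not FOM) is
summed so the cutoff-0 limit is exactly the whole-band power and the
correlation exactly 1. It is computed within subject, across epochs;
averaging across subjects is the caller's job.

## Averaged power features

PSD by Hann periodogram per 5 s epoch, averaged over epochs; absolute band
power by trapezoid integration, total over 0.5–50 Hz; relative power =
band/total. Cordance uses the classic channel-space convention: z-score
absolute and relative band power *across channels within subject and
band*, then average the two z-scores per channel (the z-scoring axis is a
config-visible choice; the alternative across-subject axis is not the
default). PEC band-passes each pair (order-4 Butterworth, zero-phase),
takes analytic signals per epoch, projects one channel's analytic signal
off the other's instantaneous phase (pointwise orthogonalization), Pearson-
correlates the amplitude envelopes over concatenated epochs, and averages
the two directions — symmetric by construction, zero for identical
channels (the orthogonalized envelope vanishes; treated as correlation 0),
and near zero for independent channels. Envelopes are not log-transformed
by default.

## Prediction protocol

Features: 4 SEF × 3 bands × 8 channels = 96 columns (channel-major,
band-minor, feature-innermost order) plus baseline HAM-D for SEF-containing
sets; APF sets add 10 per-channel power/cordance columns × 8 and 28 pairs
× 3 bands of PEC. Columns are z-scored and missing values imputed by the
mean of the 2 nearest rows (Euclidean distance over mutually observed
features, via scikit-learn's KNN imputer); statistics come from training
rows only. Subjects split 2/3–1/3 stratified by responder flag; 3-fold
stratified CV grid search over regularization strength {0.1, 0.3, 1, 3,
10}, L1 ratio {0.1, 0.5, 0.9}, intercept {on, off} (the grid brackets the
reference selection α=3.0, l1=0.5, no intercept) under negative RMSE;
ties break toward the larger α, then larger L1 ratio (the sparser model),
then no intercept. α=0 grid points are solved by OLS and l1=0 points by
the ridge closed form (the coordinate-descent objective reduces to ridge
with penalty α·n), so the penalty limits are exact.

Both phases get one-sided permutation tests, p = (#{null ≥ observed} + 1)
/ (n_perm + 1). The training phase permutes the *full procedure*: each
permutation shuffles outcomes together with their responder flags,
re-stratifies the folds, and reruns the whole grid search; the statistic
is the selected best CV score. This matters for calibration: refitting
only the selected hyperparameter point leaves the selection optimism (max
over 30 grid points) and the stratification advantage (folds balanced on a
deterministic function of the outcome) in the observed statistic, and
measured null p-values then concentrate near 0.1–0.2 instead of being
uniform. The held-out phase refits at the fixed selected parameters
(selection happened on training data, outside that statistic) and
evaluates on the test rows. Permutation importance is the mean RMSE
degradation when a single (training-set) column is shuffled, ranked by
absolute value with alphabetical tie-breaks.

Reports carry both r² conventions: the coefficient of determination
(`r2`, can be ≤ 0 for constant or mis-scaled predictions) and the Pearson
correlation between predicted and true %change (whose square is the r²
convention used when comparing against published linear models of this
outcome). The whole protocol is driven by independent RNG streams spawned
from one seed; identical inputs and seed give byte-identical JSON reports.

All randomness in the pipeline flows from named seeds in the config; there
is no hidden global RNG state.

## Post-hoc biomarker statistics

The top-k (default 5) features by absolute permutation importance are
examined outside the model: Pearson correlation of each SEF feature with
%change, Bonferroni-corrected across the tested features (Holm available);
for features surviving correction, responder/non-responder and
remitter/non-remitter contrasts by Student pooled-variance t-test,
one-sided in the direction the correlation sign implies. Patient-control
comparisons use greedy nearest-age matching without replacement, controls
processed in seeded random order, ties to the earlier index.

## Numerical and degenerate-input policy

Zero-median power (e.g. an all-zero channel) flags the channel degenerate
and sets its FOM to 0 rather than dividing by zero. Zero-variance feature
columns z-score to 0 with a warning. Zero-variance correlation inputs
return NaN. PEC on a flat channel returns NaN; a vanishing orthogonalized
envelope contributes correlation 0. Grid points with non-finite CV loss
are skipped and logged. The permutation-test hot path solves the
elastic-net grid along a warm-started descending-α path at tolerance 1e-4
(observed and null statistics use the identical routine; agreement with
the cold-start reference is ~1e-6 on the score).

## Problem sizes used by the test suite and acceptance script

Event-recovery checks use one 8-channel, 100-epoch (500 s) recording;
duration-ordering uses 20 paired seeds of 30-epoch recordings; the
treated-arm power check runs the full EEG pipeline on n=82 subjects × 30
epochs with 500 permutations; null calibration uses 20 feature-level
placebo cohorts (n=94) with 200 permutations each. These sizes were chosen
so each property is measured with comfortable statistical margin on a
single CPU.

## Known limitations

- The background contains no ocular/EMG artifacts, no line noise, no
  cap-geometry or site differences, and — by design — no spontaneous
  suprathreshold transients; real-data event rates at 6× median include a
  background-crossing component the generator deliberately lacks.
- The %change distribution is a nominal calibration (mean −40, sd 25,
  ≈ 36% responders), not a fit to any trial's empirical distribution.
- Week-1 change analyses, binary classifiers (KNN/SVM/RF), support-vector
  regression, source localization, and ICA are out of scope.
- Held-out metrics on n≈82 with a single 1/3 split are split-luck noisy;
  the protocol reports one split per seed rather than averaging splits,
  mirroring the reference procedure.
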