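# Methods

`nodulebci` implements an offline P300 brain–computer-interface pipeline
for reading lung-CT image tiles: an interpreter watches a rapid serial
visual presentation (RSVP) of CT tiles, rare nodule-bearing tiles evoke a
prefrontal positive deflection around 300 ms (a P300-type response), and
the pipeline detects those responses from multichannel EEG. Because no
recorded human data ship with the package, every stage is validated against
a synthetic-session generator with known ground truth.

## Synthetic oddball sessions

`synthetic.generate_oddball_session` emulates the acquisition protocol:

- **Timing.** Stimulus onsets every 200 ms (the protocol's display period),
  1000 Hz sampling, one second of padding on each side.
- **Composition.** Exact-count oddball scheduling: each image identity
  appears exactly `n_repetitions` times (default 13, the protocol's
  repetition optimum) and `round(n_identities × target_ratio)` identities
  are targets (default ratio 1:5 targets to background, i.e. 1/6 of
  events). The event order is a seeded permutation, so class counts are
  deterministic while order is random — matching blocks that present the
  two stimulus types "in a proportional order" rather than i.i.d. draws.
- **Background.** Per-channel 1/f noise (power exponent α = 1, synthesised
  in the frequency domain, scaled to `noise_sd` µV) plus an optional 10 Hz
  rhythm (2 µV default, random phase per channel). 1/f is the standard
  EEG surrogate; the protocol itself does not specify background
  statistics.
- **Target response.** A Gaussian positive half-wave with FWHM 40 ms
  peaking 300 ms after onset, spanning roughly the 280–320 ms window in
  which the target response is reported to peak. Channel topography is
  prefrontal-dominant: the frontal quarter of the montage has weight 1 and
  the rest decays linearly (`default_frontal_weights`).
- **Not modelled:** volume conduction/head geometry, eye-blink and EMG
  artifacts, latency jitter, habituation over repetitions. Passing tests
  therefore demonstrate correct recovery of a time-locked transient in
  1/f-type noise — not performance on real recordings, where artifacts and
  latency variability would reduce accuracy.

A synthetic CT generator produces 16-bit stacks with a bimodal
(soft-tissue / lung) histogram and bright nodule disks inside the lung
fields; it exists to exercise the presentation module and is labelled
synthetic throughout.

## Preprocessing

Resample to 256 Hz (polyphase, rational-factor), common average reference,
then a 4th-order Butterworth 0.5–48 Hz bandpass applied forward–backward.
Zero-phase filtering matters because the response latency (280–320 ms) is a
feature; the doubled response gives ≈ −22 dB at 60 Hz for fs = 256.
Epochs are cut at (−200, 800) ms around each onset (half-open sample
windows, 0-based), with the (−200, 0) ms per-channel baseline mean
subtracted (configurable, can be disabled). Repetitions of one image
identity can be averaged before classification; averaging R independent
epochs shrinks noise by ≈ √R, which is the protocol's rationale for
repeating images.

Note that the common average reference attenuates any response component
shared across channels: with the default topography roughly half of the
raw deflection survives on the frontal channels (and posterior channels
acquire a mirrored negative deflection, which is itself informative).

## Multivariate empirical mode decomposition

`memd.memd` sifts all channels jointly so every channel receives the same
number of intrinsic mode functions with matched frequency content:

- **Directions.** K unit vectors (default 64; the pipeline uses a smaller
  set for per-epoch work) from a Hammersley sequence with a seeded
  Cranley–Patterson rotation, mapped through the inverse normal CDF and
  normalised. The set is *antithetic* (each direction paired with its
  negation), so projections contribute their maxima and, via the paired
  direction, their minima; the envelope mean of a symmetric oscillation
  then cancels as in classic bivariate sifting.
- **Envelopes.** For each direction, the local maxima of the projected
  signal anchor a natural cubic spline through the multichannel signal
  values at those time points; extrema are mirrored about both edges to
  suppress end swings. The envelope mean m(t) averages over all usable
  directions; directions whose projection has fewer than two maxima are
  skipped.
- **Stopping.** A sift ends when ‖m(t)‖/‖d(t)‖ < 0.05 (channel-wise
  Euclidean norms) at ≥ 95 % of samples, or after 15 sift iterations
  (the proto-IMF is then accepted and logged). The decomposition ends at
  `max_imfs` or when the residual has fewer than three extrema along every
  test projection.
- **Guarantees.** Reconstruction (ΣIMF + residual = input) is a telescoping
  identity, exact to floating point; mode-count alignment is structural.

## Time–frequency features

Per channel, each IMF's analytic signal (frequency-domain construction of
the Cauchy-principal-value Hilbert transform) yields amplitude a_k(t),
unwrapped phase θ_k(t) and instantaneous frequency w_k(t) = dθ/dt (central
differences × fs). Squared amplitudes are accumulated on a 0.5 Hz grid
(bins centred on half-Hz multiples covering 0.5–47.5 Hz) to form the
Hilbert spectrum H(w, t); band energy IES(t) integrates H over a band and
the marginal spectrum MS(w) integrates over time, so total MS mass equals
total H mass exactly. Bands: δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–48 Hz
(half-open, decided by bin centre — an exact partition).

The per-epoch feature vector is the concatenation [F_t | F_s | Q | S |
cross-SampEn] with a documented name layout:

- **F_t (per channel):** mean and SD of the signal over the epoch; mean
  amplitude in the stimulus-locked response window (default 280–320 ms),
  the latency range whose amplitude difference separates target from
  background viewing; mean and SD of Hjorth mobility
  (√(Var(y′)/Var(y)), y′ = first differences × fs) over 250 ms windows.
- **F_s (per channel):** mean and SD over time of each band's IES, and
  mean and SD of MS over the grid.
- **Pair features** (default: all pairs among the first 3 frontal
  channels) on the band-of-interest signal — the sum of IMFs whose mean
  instantaneous frequency lies in 0.5–8 Hz (δ/θ, where the response
  lives): phase-locking value Q = |mean e^{j(θ1−θ2)}|, frequency-locking
  value S = |mean e^{j(w1−w2)Δt}| (modulus convention, both in [0, 1]),
  and cross-sample entropy.
- **Cross-sample entropy:** −ln(B^{m+1}/B^m) with Chebyshev template
  distance, m = 2, tolerance R = 0.2 × pooled SD of the two series, and
  the same N−m template count at both lengths — making the statistic
  symmetric in its arguments. B = 0 at either length flags the value
  undefined (NaN), never silently zero.
- **Flagged values** (undefined mobility, entropy, or locking values) are
  imputed with 0 and a parallel 0/1 indicator column is appended for each
  flaggable entry.

## Stacked classification

Stratified 1:1 train/test split (the protocol's ratio). Five base
families: RBF SVC with probability calibration, 200-tree random forest, L2
logistic regression, 5-NN, and 100-round AdaBoost on depth-1 stumps.
Scale-sensitive families (SVC, logistic, k-NN) are wrapped with a
standardiser and an ANOVA feature screen (top 16 features, fitted inside
each fold): epoch feature vectors are high-dimensional relative to the
number of classification units an oddball session yields, and distance-
and margin-based learners dilute badly without screening. The level-2
matrix is built by stratified 5-fold out-of-fold prediction — each
training sample's level-2 feature comes from the one fold model that never
saw it — and test-set level-2 features average the five fold models per
family. The meta-learner is logistic regression on the five base scores
(pluggable); base scores are continuous positive-class probabilities so
ranking information survives for ROC analysis.

## Evaluation

SEN = TP/(TP+FN), SPE = TN/(TN+FP), and the combined-numerator
FPF = (FP+FN)/(TP+FP+TN+FN) — a misclassification-style rate kept in this
form deliberately; the conventional FPR = FP/(FP+TN) is exported alongside
as `fpr_conventional`. Zero-denominator metrics are NaN, never 0. ROC
curves sweep the unique scores (ties grouped) with trapezoidal AUC, which
equals the Mann–Whitney rank statistic in tie-free data (tested against an
explicit pair-counting oracle). The default decision threshold is 0.5.

## CT presentation

`window_map` maps [level − width/2, level + width/2] linearly to [0, 255]
with clamping and round-half-up (a pixel at the level maps to 128).
Mode 1 windows on the frame's own mean with width 4σ (floor 1 intensity
unit for flat frames); Mode 2 uses the standard radiological lung window
(level −600 HU, width 1500 HU; an intercept converts raw unsigned stacks);
Mode 3 emits the lung-window frame plus level∓200 companions, pixelwise
ordered. The hexagon search path groups image tiles into concentric
hexagonal rings (odd-row-offset axial coordinates) and visits them
outside-in, each ring in fixed angular order — a documented stand-in
traversal with a stated locality property, not a reconstruction of any
published hexagon algorithm. Presentation plans repeat each selected tile
a fixed number of times at a constant 200 ms onset spacing, honour the
1:5 target ratio exactly, and never place two targets adjacently when the
ratio is ≤ 1/3.

## Orchestration and reproducibility

`pipeline.run_pipeline` executes simulate → preprocess → features → train
→ evaluate with one top-level seed fanned out to per-stage sub-seeds via
`numpy.random.SeedSequence.spawn`. Configurations are strict dataclasses
(unknown keys rejected), serialised back to YAML next to the outputs with
a config hash, a JSON-lines stage log, features CSV, model bundle, metrics
JSON and ROC TSV. Reruns with the same config and seed reproduce the
metrics.

## Study sizes and numerical choices

The parameter-recovery experiment (`run_synthetic_experiment`) uses 240
image identities × 13 repetitions = 3120 epochs per session at 8 channels,
repetition-averaged to 240 classification units (40 targets), with the
response amplitude set to half the background noise SD. These sizes are
the package's scaled-down study: enough target units for a stable test
AUC while keeping a session's feature extraction in the tens of seconds.
The per-epoch MEMD inside this experiment uses K = 8 directions and at
most 6 IMFs; the library defaults (K = 64, 8 IMFs) are used for the
decomposition-quality checks.

Degenerate inputs are handled explicitly: constant signals are residuals
for MEMD (no extrema), all-zero series flag their analytic phase as
undefined, constant series flag mobility as undefined, and classifiers
refuse single-class inputs and folds that would lose a class.

## Known limitations

- The synthetic generator omits artifacts, latency jitter and inter-subject
  variability; real-EEG performance is expected to be lower.
- The hexagon traversal is a stand-in with stated properties, not a
  faithful reproduction of the cited search path.
- MEMD envelope behaviour near the edges depends on the mirror extension;
  very short epochs (< ~1 s at 256 Hz) leave few extrema per projection
  and coarser IMFs.
- Reported detection metrics from human experiments (e.g. trained-reader
  sensitivity/specificity on real CT) summarise undeposited data and are
  outside the package's computational scope.
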