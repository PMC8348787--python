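# Methods

This note documents the models, conventions and numerical choices behind
`mpar`: what each pipeline stage computes, which parameters matter, what
the synthetic cohort does and does not emulate, and where the design was
genuinely open.

## Sensor model and file conventions

A recording is one activity bout from one subject: a 50 Hz stream of six
IMU channels (3-axis accelerometer, 3-axis gyroscope) plus a 1 Hz
skin-temperature channel, all nominally quantised at 16 bits. Sensor
units are not standardised by the emulated hardware description, so the
toolkit adopts accelerometer g and gyroscope degrees/second and declares
both in the file header (`# units_acc=g`, `# units_gyro=dps`); every
downstream statistic is unit-agnostic, so this is a labelling choice,
not a modelling one. The 1 Hz temperature track is forward-filled onto
the 50 Hz tick grid so a single flat CSV holds all channels; the only
consumer of temperature is the per-window mean, for which the
forward-filled and raw-1 Hz versions are numerically near-identical.
Timestamps are seconds from bout start — the pipeline uses only relative
time. Quantisation is recorded as metadata; samples are stored as
decimals and never re-quantised, since all window statistics operate on
real-valued samples.

Validation enforces: strictly increasing timestamps, temperature
constant within each one-second span, and activity labels drawn from the
ten-class MPA vocabulary.

## Windowing

Windows hold exactly N = window_seconds × 50 samples (50 or 100);
overlapped mode uses stride N/2 (25 or 50 samples, i.e. 0.5 s or 1 s of
shared signal), non-overlapped stride N. The window count over T samples
is floor((T − N)/stride) + 1. Trailing samples that do not fill a window
are dropped rather than padded: the feature formulas assume exactly N
samples, and padding would bias every moment statistic. Windows never
span bout boundaries, because labels are per bout. A recording shorter
than one window yields an empty window list with a warning, not an
error — short bouts are legal field data.

## The 43-feature descriptor

Thirteen families, in a fixed canonical order (family sizes
4,3,3,3,3,3,3,3,3,6,3,3,3). Conventions that required a decision:

- **Standard deviation** uses the population form
  sqrt((1/N)Σ(S_i−μ)²) — the printed formula, not the sample (N−1)
  estimator.
- **Skewness** uses the standard third standardised moment with 1/N
  normalisation. Formulations exist that omit the 1/N (while including
  N in kurtosis one line away); for internal consistency the normalised
  form is the default and `FeatureSpec(skew_literal=True)` provides the
  unnormalised variant. Kurtosis is Σ(S_i−μ)⁴/(Nσ⁴), i.e. m₄/σ⁴
  (Fisher's β₂, not excess).
- **Degenerate windows** are legal (a subject laying still produces
  near-constant axes): skewness, kurtosis, entropy and the cosine
  similarity of a zero-norm pair are defined as 0, the grouped Q1 of a
  constant window is that constant. Degeneracy is detected at a
  float-rounding-scale tolerance (64·eps·max(1, |μ|)) rather than exact
  σ = 0, because the mean of N identical floats need not subtract to
  exactly zero.
- **Zero crossings** count strict sign changes only; a sample exactly
  at zero never produces a crossing, exactly as the defining predicate
  states.
- **Spectral features** are computed from the mean-removed acceleration
  magnitude sqrt(ax²+ay²+az²). Magnitude keeps the family
  orientation-invariant and yields exactly six features rather than
  eighteen. From the one-sided DFT magnitudes |H(k)|, k = 1..N/2:
  `peakf` is the maximum, `lowf1..lowf3` the first three non-DC bins,
  `medf` and `highf` the band means over (5, 15] and (15, 25] Hz. The
  band edges evenly cover the 0–25 Hz one-sided range at 50 Hz sampling
  and are configurable on `FeatureSpec`. Whether "peak" should mean the
  peak magnitude or the frequency at which it occurs is ambiguous in
  common usage; `peakf` reports the magnitude, and
  `fft_peak_frequency()` exposes the frequency as a diagnostic extra.
- **Entropy** is Shannon entropy in bits over a 16-bin equal-width
  histogram of the window (empty bins skipped). A variant with an extra
  1/N factor appears in some formulations; it makes entropy
  window-length dependent without an evident motivation, so it is
  available only as `FeatureSpec(entropy_literal=True)`.
- **Grouped first quartile** uses Q1 = l + (h/f)(N/4 − C) over 10
  equal-width classes of [min, max], with l, f, C taken at the class
  containing the ⌈N/4⌉-th ordered sample. The grouped formula presumes
  binned data; 10 classes are stable for N ∈ {50, 100} and agree with
  the order-statistic quartile to within one class width.
- **Tie-breaking** for max/min locations (peak time difference) is
  first occurrence, for determinism.

Extraction is vectorised: the per-window scalar operations delegate to
batch kernels over stacked `(n_windows, N)` arrays, so a full cohort
(tens of thousands of windows) featurises in seconds, and the batch
path provably equals mapping the scalar path window by window (tested).

## Classifier harness

The five reference configurations (1-NN Manhattan; depth-50 decision
tree; 100-tree random forest; grow/prune rule induction at ratio 0.95;
gradient-boosted trees, 100 iterations, depth 50) map onto scikit-learn
estimators. Two mappings deserve note:

- **Rule induction** has no scikit-learn implementation; it is realised
  as a grow/prune tree: fit an unpruned tree on a 95% grow split,
  choose the cost-complexity pruning strength that maximises accuracy
  on the held-out 5% prune split (up to 16 candidate alphas along the
  pruning path), and refit. Each root-to-leaf path of the pruned tree
  is one induced rule; the grow/prune ratio is honoured directly.
- **Gradient boosting** uses histogram gradient boosting
  (`HistGradientBoostingClassifier`, max_iter 100, max_depth 50) — the
  same model family; exact non-histogram boosting at depth 50 over ten
  classes is computationally out of reach on one CPU without changing
  the model.

Splits are repeated random window-level partitions at 90–10, 80–20 or
70–30, stratified by class by default (ten imbalanced classes make
unstratified small test sets unstable; the unstratified mode remains
available). The repeat count defaults to 10. Window-level pooling is
the emulated protocol and inflates accuracy — windows of one bout can
land on both sides of the split; `SplitPlan(by_subject=True)` provides
the leakage-free leave-subjects-out design. All randomness (splits,
forests, boosting, grow/prune) derives from one master seed, and each
(seed, repeat) pair maps to an independent derived stream, so any grid
cell reproduces itself exactly in isolation.

Results carry per-repeat accuracies, the pooled 10×10 confusion matrix
(true × predicted counts; accuracy = trace/total, per-class recall =
diagonal/row sum) and a row-normalised view, since confusion matrices
are reported in both conventions in practice.

## Monitoring

The alert rule is: an alert fires at the first moment a proscribed
label has been predicted continuously for at least `sustain_seconds`
(the emission is back-dated to onset + sustain); the same continuing
episode re-alerts at window ends spaced at least `cooldown_seconds`
apart; the episode — and its cooldown state — resets as soon as a
different label appears. Defaults are sustain 60 s, cooldown 600 s and
an *empty* proscribed set: which activities are proscribed, and for
which trimester, is a clinical judgement that belongs in configuration
(a YAML policy file), not in code. Prolonged standing (MPA10) is the
documented example policy. An optional centred majority-vote smoother
(odd width, ties keep the centre label) damps single-window prediction
flicker before the rule is applied. Message delivery is a sink
interface with in-memory, logging and file implementations standing in
for the cellular-modem transport of a deployed system.

## Synthetic cohort

Per activity class, the generator emits: a gravity projection encoding
wrist orientation, up to three sinusoidal movement components (per-axis
amplitudes, class frequency), Gaussian sensor noise, and a slowly
drifting temperature baseline. Per-bout lognormal-style jitter of
amplitudes (±18%) and frequencies (±6%) plus random phases plays the
role of subject and bout variability. The default design mirrors the
emulated study: 61 subjects, six activity bouts each, 2–5 minutes per
bout, with subject metadata (trimester, age band, occupation, anemia)
drawn from plausible categorical distributions and carried — but never
modelled — through the pipeline.

Three class near-collisions are engineered in deliberately, mirroring
the confusion structure reported for the real cohort: stairs (MPA1)
close to walking (MPA7); side bending (MPA9) and standing (MPA10) near
hands exercise (MPA4) in wrist-motion energy; laying (MPA6) and front
bending (MPA8) strongly distinct. Amplitude/frequency/noise values are
desk-calibrated wrist plausibilities chosen once, with the calibration
target that the pipeline's contract holds on the defaults (random
forest ≥ 0.90 on pooled 80–20 splits) while 10× noise inflation
degrades separability measurably.

What the generator does **not** emulate: biomechanically realistic
gait, inter-axis phase structure of real arm swing, trimester effects
on movement, sensor drift/saturation, non-stationarity within a bout
beyond jitter, or realistic class imbalance. Consequently, passing
accuracy thresholds on synthetic data demonstrates that the pipeline is
correct and discriminative signal survives it — not that comparable
accuracy would be reached on clinical recordings.

## Problem sizes

Desk-scale defaults keep every entry point minutes-fast on one CPU: the
benchmark used by the acceptance checks generates the full default
cohort (61 subjects, ≈ 366 bouts, ≈ 3.9 M ticks), windows it at 2 s
non-overlapped (≈ 38 k windows), and evaluates classifiers on a seeded
stratified subsample of 12 000 feature rows over ten 80–20 splits; the
chance-level control uses 200 rows per class with labels permuted, 20
repeats. Feature extraction itself is vectorised and handles the full
window table in under half a minute; the subsample exists because
fitting five classifiers × ten repeats dominates runtime, and accuracy
estimates stabilise well below the full table size.

## Known limitations

- Window-level splits leak bout identity; headline accuracies on the
  synthetic benchmark are near ceiling partly for this reason (the
  leave-subjects-out option quantifies the gap).
- The 43-feature schema is fixed; no feature selection or learned
  features are provided.
- The monitoring rule is purely label-driven; it does not weigh
  prediction confidence or fuse temperature.
- Synthetic signals are stationary sinusoid-plus-noise processes; see
  the generator caveats above before reading accuracy numbers as
  clinical performance.
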