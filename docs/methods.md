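# Methods

`walksev` implements a remote-monitoring severity pipeline for multiple
sclerosis (MS) ambulation: daily smartphone two-minute walk tests (2MWT) are
transformed into a continuous disease-severity estimate by a convolutional
epoch classifier, and per-subject severity time series are smoothed and
tested around clinical events.  Because no public accelerometer cohort of
this design exists, the package ships a synthetic-cohort generator that
reproduces the *statistical structure* the analysis assumes; every
experiment in `analysis/` and every quantity in `scripts/acceptance.py` is
computed on synthetic cohorts.

## The severity model

Each 120-second triaxial recording (50 Hz, units of g) is partitioned into
epochs of 128 samples (2.56 s) with 50% overlap; a trailing partial window
is discarded, so a full test yields floor((6000−128)/64)+1 = 92 epochs.
The model input per epoch is the 128×4 tensor
X = (a_x, a_y, a_z, ‖a‖)ᵀ, the three axes plus the orientation-invariant
magnitude.

The classifier is a causal 1-D DCNN: four convolutional blocks
(conv→batch-norm→ReLU), with 32 filters of width 9 (l2 penalty λ = 1e-3 on
the kernel) in block 1, 64×3 in blocks 2 and 3, 128×6 in block 4, and
max-pooling (pool 2, stride 2) after blocks 2 and 4; a dense softmax maps
the flattened features to the three classes k ∈ {hc, mild, mod}
(healthy control, mildly disabled EDSS < 3.5, moderately disabled
EDSS ≥ 3.5).  Causality is realised by left zero-padding so output length
equals input length.  Batch normalisation uses momentum 0.99 and ε = 1e-2.
Training minimises categorical cross-entropy under Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8).  Orientation augmentation applies one
fresh rotation, drawn uniformly from SO(3) via normalized quaternions, to
the axis triplet of every training epoch on every pass; the ‖a‖ channel is
recomputed (it is invariant by construction).  No augmentation is applied
at prediction time.

The network is implemented directly in NumPy (`walksev.nn`): causal
convolution as shifted GEMMs, hand-written backward passes verified against
finite differences, and float32 arithmetic.  Inference is deterministic
given the weights up to float32 GEMM blocking (differences below 1e-7 when
the batch composition changes).

Design choices where the architecture description was open:

* activation: ReLU after each batch-norm (the field default for DCNN
  blocks); layer order conv→BN→activation;
* argmax ties break toward the lower (less severe) class;
* the l2 penalty applies to the block-1 kernel only;
* block 1 is trainable by default, with a `freeze_block1` flag and a
  weight-loading hook for injecting pre-trained kernels.

### Training from scratch and BN recalibration

The reference optimiser setting lr = 1e-5 is a fine-tuning rate (the design
assumes a network pre-trained on a public human-activity-recognition
corpus; pre-training is out of scope here and replaced by the weight-
loading hook).  Training from random initialisation at 1e-5 would need
impractically many passes, so the experiment configurations train from
scratch at lr = 1e-3; `ModelConfig` keeps 1e-5 as the documented default
and both are freely configurable.

With short training runs the momentum-0.99 exponential running statistics
of batch normalisation remain dominated by their initialisation, which
mis-calibrates inference mode.  After training, the running statistics are
therefore replaced by population statistics computed in one pass over (a
sample of) the training set under the final weights — the standard
recalibration used with weight averaging.  This removes the dependence of
inference quality on training length.

## The daily severity and its reduction

For the N epochs of one test day d, the daily severity is the mean of the
per-epoch argmax classes:

    ŷ_d = (1/N) Σₙ argmaxₖ p(y = k | xₙ),   0 ≤ ŷ_d ≤ K = 2.

The mean is over hard argmax labels, not posterior probabilities, so ŷ_d
touches an endpoint only when every epoch agrees.  A missing day is an
error, not zero severity.  Per-subject summary severity is the mean of ŷ_d
over *observed* days; imputed days are excluded from any evaluation.

An important consequence of the bounded scale: a subject whose gait already
reads at the ceiling (ŷ_d ≈ 2) cannot register further worsening.  The
event-sensitivity experiment therefore follows the observed relapse
phenomenology — a moderate-group subject whose pre-relapse severity reads
mild and rises to moderate at onset (see below).

## Longitudinal trends

Each subject's dated series of ŷ_d is processed as:

1. **Piecewise linear interpolation (PLI)** fills every integer study day
   strictly inside the observed span; no extrapolation outside it.  Filled
   entries are flagged `imputed`.  PLI is idempotent and exact on linear
   series.
2. **Centred moving average (MAF)** of odd order 2N+1 (default 7 days,
   N = 3): ẑ[i] = mean of ŷ over days i−N…i+N.  Imputed days are included
   here — that is what they exist for.  At the series edges the window
   shrinks to the available days so no days are dropped (the alternative,
   truncating N days per edge, discards real data; trend values everywhere
   on the observed span match how such trends are plotted over whole
   studies).
3. **Event splits**: observed (never imputed) severities are partitioned at
   an event day; the event day itself belongs to the *after* side because
   the event "onsets" on that date.

## Statistics battery

* Association with EDSS: Pearson r and Spearman ρ with two-sided p-values
  plus the least-squares line; r² is computed as r·r from the same Pearson
  path.  Healthy controls carry no EDSS, so the association is reported
  both MS-only and all-subjects with HC coded EDSS 0 (an EDSS of zero means
  a normal neurological exam).
* Group differences: Kruskal–Wallis by ranks with tie correction.
* Before/after an event: a Brown–Forsythe test *by medians* (the
  Levene-type statistic on absolute deviations from the group median)
  gates the t-test — Student's when variances are homogeneous (BF
  p ≥ α = 0.05), Welch's otherwise; a Mann–Whitney U test (exact null for
  tie-free samples of ≤ 8 per side, otherwise the normal approximation
  with tie and continuity correction) is always computed.  All tests are
  two-sided.  Two constant, equal sides are reported `not computable`
  rather than as NaN.  No multiple-testing correction is applied by
  default; Holm adjustment is available.

All tests are delegated to scipy/statsmodels; the test suite verifies each
against hand formulas and 10⁴-permutation oracles, and calibrates the
type-I error of the gated battery on 1000 null replicates.

## Cross-validation protocol

Stratified, subject-wise, 5-fold CV: whole subjects are dealt round-robin
to folds within each severity group after a seeded shuffle, so fold group
counts differ by at most one subject; a group smaller than k degrades
gracefully and is noted in the plan.  Within each fold's training set,
roughly 10% of subjects are held out for validation (early stopping on
validation loss).  Every epoch of every recording of the out-of-sample
subjects is predicted, reduced to ŷ_d and then to one out-of-sample mean
severity per subject.  Leakage is asserted programmatically in the CV loop
and audited over 100 random plans in the tests.

## The synthetic cohort generator

The generator emulates what the pipeline must cope with, not gait
biomechanics:

* **Signal model.** Per step, an instantaneous cadence frequency is drawn
  (one draw per step; SD = stride-to-stride variability), and harmonics are
  placed at the step and stride frequencies: the dominant, asymmetry-
  modulated step harmonic plus its second harmonic on the device vertical
  axis (with the +1 g gravity offset), a stride+step mix antero-
  posteriorly, a stride component medio-laterally, plus white noise per
  axis.  One rotation, uniform over SO(3), emulates the arbitrary but
  fixed phone orientation of a test.  Waveform and orientation randomness
  come from separate streams, so noise-free parameter sets give
  orientation-independent ‖a‖ traces.
* **Strata.** Default parameters (step frequency / SD / amplitude /
  asymmetry, noise SD 0.05 g): healthy 2.0 Hz / 0.03 / 0.35 g / 0.05;
  mild 1.85 / 0.08 / 0.29 / 0.15; moderate 1.65 / 0.16 / 0.22 / 0.30 —
  slower, weaker, more variable and more asymmetric with severity,
  matching the qualitative gait phenomenology of MS (values chosen once to
  make the strata separable through cadence and variability; the
  separability statistic `cadence_cv`, the coefficient of variation of
  peak-picked step intervals, orders the group means hc < mild < mod).
  Per-subject parameters are log-normally jittered (4% SD) around the
  group defaults; EDSS is drawn per stratum (mild 1.7 ± 0.8 clipped to
  [0, 3], moderate 4.2 ± 0.7 clipped to [3.5, 5.5], half-point grid).
* **Cohort.** Default composition 24 HC / 52 mild / 21 moderate over 168
  study days (24 weeks); daily test performed with per-group adherence
  0.90/0.85/0.80 (and an optional post-event adherence to emulate the
  observed drop after adverse events).  All randomness derives from the
  cohort seed; output is bit-reproducible.
* **Relapses.** A relapse at day r multiplies the gait parameters for a
  finite window (default 21 days): frequency ×0.85, frequency SD ×2,
  amplitude ×0.75, asymmetry +0.25 — roughly the mild→moderate parameter
  gap, i.e. a one-EDSS-point acute worsening.

What the generator does *not* emulate: realistic biomechanics, turning,
pauses, device placement differences, within-day repeated tests, diurnal
effects, or gradual progression.  Passing tests therefore demonstrate that
the pipeline's machinery is correct and recovers planted structure; they
say nothing about classification accuracy on real patients.

## Experiment scales

The reference experiments are sized for a single CPU:

* Parameter recovery: 30 subjects (10 per stratum) × 28 days; training
  samples 5 epochs per recording for 6 passes (batch 64, lr 1e-3, patience
  3); evaluation uses all 92 epochs of every out-of-sample recording.
* Event sensitivity: a scorer trained on 12 subjects × 6 days (8 epochs
  per recording, 12 passes), then 50 relapsing moderate-group subjects
  over 28 days with the relapse at day 14 and adherence 0.8.  Their
  baseline gait is mild-typical: the bounded severity scale can only
  register worsening below its ceiling, and the relapse shifts them to
  moderate-typical gait.
* Null calibration: 1000 replicates of the gated battery on two N(1, 0.3²)
  samples of 15 per side.

## Numerical notes and limitations

* Epoch arrays are float32; GEMM-order differences across batch
  compositions perturb posteriors below 1e-7.
* The MAF edge rule (shrinking window) slightly increases edge-trend
  variance relative to interior days.
* `cadence_cv` returns NaN when fewer than three peaks are found (tiny or
  pathological recordings).
* Severity is a naïve ordinal reduction: averaging argmax classes discards
  posterior uncertainty, and its [0, 2] range saturates for clearly
  moderate gait (see the event-sensitivity design above).
* Days with two tests would be averaged into one ŷ_d before imputation;
  the simulator never produces them.
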