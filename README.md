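# walksev

Ambulatory disease-severity estimation from smartphone two-minute walk
tests (2MWT), with longitudinal trend monitoring — aimed at remote
monitoring of people with multiple sclerosis (PwMS), whose gait impairment
fluctuates on time scales that infrequent clinic visits cannot resolve.

A daily, at-home 2MWT recorded by a phone's accelerometer is turned into a
continuous severity estimate in three steps:

1. **Epoching.** Each 120 s triaxial recording (50 Hz) is cut into 128-
   sample (2.56 s) windows with 50% overlap; each window becomes a 128×4
   tensor (a_x, a_y, a_z, ‖a‖).
2. **Classification.** A causal 1-D deep convolutional network — blocks of
   conv→batch-norm→ReLU with 32×9, 64×3, 64×3 and 128×6 filters, max-pooling
   after blocks 2 and 4, dense softmax over k ∈ {hc, mild, mod} — labels
   every epoch, with random SO(3) rotation augmentation during training for
   orientation invariance.
3. **Severity.** The daily severity is the mean of per-epoch argmax
   classes,

       ŷ_d = (1/N) Σₙ argmaxₖ p(y = k | xₙ),  0 ≤ ŷ_d ≤ 2,

   a continuous value interpolating healthy → mild → moderate.

Per-subject series of ŷ_d are gap-filled by piecewise linear interpolation,
smoothed by a 7-day centred moving average ẑ, and tested around clinical
events (relapses) with a variance-gated battery: Brown–Forsythe by medians
chooses between Student's and Welch's t-test, alongside a Mann–Whitney U
test.  Models are evaluated only under stratified, subject-wise 5-fold
cross-validation, so no subject's data appears on both sides of a fold.

No public dataset of this design exists, so the package includes a
synthetic-cohort generator (three severity strata with separable cadence,
amplitude and variability; daily tests over 24 weeks; per-subject
adherence; random phone orientation per test; optional relapse shifts on
known dates) used by every experiment and test.  The network itself is a
compact NumPy implementation (hand-verified gradients, shifted-GEMM
convolutions); see `docs/methods.md` for the full model description and
design rationale.

## Worked example

The numbered scripts under `analysis/` run the study end to end at desk
scale (a 30-subject, 28-day cohort; a few minutes on one CPU):

```
$ python analysis/01_simulate_cohort.py --seed 1
$ python analysis/02_severity_cv.py --seed 1
out-of-sample group median severities: hc=0.006  mild=1.010  mod=2.000
strictly ordered hc < mild < mod: True
Kruskal-Wallis: H=26.04, p=2.22e-06
Spearman rho (true class vs mean severity): 0.948
```

Reading this: after subject-wise cross-validation, the median out-of-sample
severity of healthy controls sits near 0, mild subjects near 1 and moderate
subjects at the scale ceiling 2 — the classifier recovers the planted
ordinal structure — and a subject's mean severity correlates strongly with
their true stratum (ρ = 0.95) and with their simulated EDSS score.
`analysis/03_longitudinal_trends.py` then shows the 7-day moving average
removing most day-to-day severity variability, and
`analysis/04_relapse_events.py` injects relapses at a known day and detects
the severity shift per subject:

```
$ python analysis/04_relapse_events.py
50 relapsing moderate subjects; 50 with computable batteries
mean severity before 0.995 -> after 1.995
t-test detects the shift at p<0.05 in 100% of subjects
```

The same pipeline is scriptable from YAML via the `walksev` CLI
(`walksev simulate`, `walksev run`, `walksev trend`); `walksev run` with no
overrides executes the reference configuration on a full synthetic
97-subject, 24-week cohort (hours of CPU, sized for completeness rather
than the desk-scale experiments above).

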