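"""Reference experiment recipes at desk scale.

These are the package's canonical study-condition experiments, shared by the
analysis drivers and the acceptance checks:

* :func:`scaled_cv_experiment` — parameter recovery: a 30-subject (10 per
  stratum), 28-day cohort under stratified subject-wise 5-fold CV with a
  reduced training budget (5 epochs sampled per recording, 6 passes,
  from-scratch learning rate 1e-3); evaluation uses every epoch of every
  out-of-sample recording.
* :func:`train_reference_model` — a classifier trained once on a small
  balanced cohort, for experiments that need a fixed scorer.
* :func:`relapse_experiment` — event sensitivity: relapsing moderate-group
  subjects whose baseline gait is mild-typical (a bounded severity scale
  can only register worsening below its ceiling; the observed relapse
  phenomenology is a mild-reading subject whose gait turns moderate at
  onset), scored daily and tested with the before/after battery.
* :func:`type_i_error_rate` — null calibration of the variance-gated
  battery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate as sim
from .crossval import ExperimentResult, make_folds, run_cv_experiment
from .epoching import epoch_recording, stack_epochs
from .longitudinal import SeverityTimeSeries, split_by_event
from .model import DailySeverity, ModelConfig, SeverityDCNN, build_model, \
    train_model
from .stats import before_after_tests


def scaled_cv_experiment(seed: int, n_per_group: int = 10,
                         study_days: int = 28) -> ExperimentResult:
    """Run the scaled parameter-recovery experiment for one seed."""
    truth = sim.make_cohort(n_hc=n_per_group, n_mild=n_per_group,
                            n_mod=n_per_group, study_days=study_days,
                            seed=seed)
    recordings = sim.simulate_cohort(truth)
    groups = {s.subject_id: s.group for s in truth.specs}
    plan = make_folds(groups, k=5, seed=seed)
    config = ModelConfig(train_epochs=6, batch_size=64, learning_rate=1e-3,
                         patience=3, seed=seed * 100)
    return run_cv_experiment(recordings, truth, config, plan,
                             train_epochs_per_recording=5)


def train_reference_model(seed: int = 21) -> SeverityDCNN:
    """Train a scorer on a 12-subject (4 per class), 6-day cohort: 8 epochs
    sampled per recording, 12 passes, learning rate 1e-3."""
    truth = sim.make_cohort(n_hc=4, n_mild=4, n_mod=4, study_days=6,
                            seed=seed)
    recordings = sim.simulate_cohort(truth)
    class_of = {s.subject_id: s.class_index for s in truth.specs}
    rng = np.random.default_rng(seed)
    epochs = []
    for rec in recordings:
        es = epoch_recording(rec)
        idx = rng.choice(len(es), size=8, replace=False)
        epochs.extend(es[i] for i in sorted(idx))
    x, index = stack_epochs(epochs)
    y = index["subject_id"].map(class_of).to_numpy()
    config = ModelConfig(train_epochs=12, batch_size=64, learning_rate=1e-3,
                         seed=seed)
    model = build_model(config)
    train_model(model, x, y, config=config)
    return model


def relapse_experiment(model: SeverityDCNN, n_subjects: int = 50,
                       seed: int = 22, study_days: int = 28,
                       relapse_day: int = 14,
                       adherence: float = 0.8) -> pd.DataFrame:
    """Score relapsing moderate-group subjects daily and run the
    before/after battery per subject around the known relapse day."""
    base = sim.DEFAULT_GROUP_PARAMS["mild"]   # below-ceiling baseline
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        jit = np.exp(rng.normal(0.0, 0.04, 4))
        params = sim.GaitParams(base.step_frequency * jit[0],
                                base.step_frequency_sd * jit[1],
                                base.amplitude * jit[2],
                                min(1.0, base.asymmetry * jit[3]),
                                base.noise_sd)
        spec = sim.SubjectSpec(f"r{i:03d}", "mod", params,
                               adherence=adherence,
                               relapse_dates=(relapse_day,))
        truth = sim.CohortTruth(specs=(spec,), seed=seed * 1000 + i,
                                study_days=study_days)
        daily = []
        for rec in sim.simulate_cohort(truth):
            x, _ = stack_epochs(epoch_recording(rec))
            cls = model.forward_probs(x).argmax(axis=1)
            daily.append(DailySeverity(rec.subject_id, rec.study_day,
                                       float(cls.mean()), len(cls)))
        series = SeverityTimeSeries.from_daily(spec.subject_id, daily)
        analysis = split_by_event(series, relapse_day)
        row = {"subject_id": spec.subject_id,
               "n_before": len(analysis.before),
               "n_after": len(analysis.after),
               "mean_before": float(np.mean(analysis.before)),
               "mean_after": float(np.mean(analysis.after)),
               "computable": analysis.computable}
        if analysis.computable:
            row.update(t_p=analysis.tests.t_p, u_p=analysis.tests.u_p,
                       bf_p=analysis.tests.bf_p,
                       welch_applied=analysis.tests.welch_applied)
        rows.append(row)
    return pd.DataFrame(rows)


def type_i_error_rate(n_replicates: int = 1000, n_per_side: int = 15,
                      alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the variance-gated t-test on two samples drawn
    from the same distribution."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(1.0, 0.3, n_per_side)
        b = rng.normal(1.0, 0.3, n_per_side)
        res = before_after_tests(a, b, alpha=alpha)
        if res.computable and res.t_p < alpha:
            rejections += 1
    return rejections / n_replicates
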