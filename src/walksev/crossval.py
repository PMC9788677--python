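"""Stratified, subject-wise cross-validation of the severity pipeline.

Whole subjects — with every epoch of every test they performed — are
assigned to exactly one of k folds, stratified by severity group, so no
subject's data can leak between training and evaluation.  Within each
fold's training set, roughly 10% of subjects are held out for validation
(early stopping).  Out-of-sample daily severities are aggregated into one
mean severity per subject, which feeds the EDSS association and group
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epoching import epoch_recording, stack_epochs
from .model import (ModelConfig, build_model, train_model,
                    DailySeverity)
from .simulate import GROUPS, CohortTruth, WalkRecording
from .stats import AssociationResult, associate_with_edss, group_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of subjects to folds plus per-fold validation subsets."""

    k: int
    assignment: dict[str, int]
    validation: dict[int, tuple[str, ...]]
    seed: int
    notes: str = ""

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        held = set(self.test_subjects(fold)) | set(self.validation.get(fold, ()))
        return sorted(s for s in self.assignment if s not in held)

    def to_dict(self) -> dict:
        return {"k": self.k, "seed": self.seed, "assignment": self.assignment,
                "validation": {str(f): list(v)
                               for f, v in self.validation.items()},
                "notes": self.notes}


def make_folds(subject_groups: dict[str, str], k: int = 5,
               validation_fraction: float = 0.1, seed: int = 0) -> FoldPlan:
    """Stratified subject-wise fold assignment.

    Subjects are shuffled within each group and dealt round-robin to folds,
    so each fold's group counts are within one subject of proportionality.
    If a group has fewer than k members, stratification for that group
    degrades gracefully (some folds simply lack it; noted in the plan).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(subject_groups) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    assignment: dict[str, int] = {}
    notes = []
    for group in sorted(set(subject_groups.values())):
        members = sorted(s for s, g in subject_groups.items() if g == group)
        if len(members) < k:
            notes.append(f"group {group} has {len(members)} < {k} subjects; "
                         "not all folds contain it")
        order = rng.permutation(len(members))
        offset = int(rng.integers(k))
        for pos, idx in enumerate(order):
            assignment[members[idx]] = (pos + offset) % k
    validation: dict[int, tuple[str, ...]] = {}
    for fold in range(k):
        train = sorted(s for s, f in assignment.items() if f != fold)
        n_val = max(1, int(round(validation_fraction * len(train))))
        pick = rng.permutation(len(train))[:n_val]
        validation[fold] = tuple(train[i] for i in pick)
    return FoldPlan(k=k, assignment=assignment, validation=validation,
                    seed=seed, notes="; ".join(notes))


@dataclass
class ExperimentResult:
    """Out-of-sample results of one cross-validated severity experiment."""

    subject_severity: pd.DataFrame            # subject_id, group, mean ŷ, EDSS
    daily: list[DailySeverity]
    association_ms: AssociationResult | None  # MS subjects only
    association_all: AssociationResult | None # HC coded as EDSS 0
    kw_h: float
    kw_p: float
    spearman_true_class: float
    fold_logs: list = field(default_factory=list)

    def group_medians(self) -> dict[str, float]:
        med = self.subject_severity.groupby("group")["severity"].median()
        return {g: float(med[g]) for g in med.index}


def _epochs_for(recordings: list[WalkRecording], subjects: set[str],
                window: int, overlap: float,
                max_epochs_per_recording: int | None = None,
                rng: np.random.Generator | None = None):
    """Stacked epochs + index for the given subjects.  Training cost can be
    bounded by subsampling epochs per recording (evaluation always uses all
    epochs)."""
    chosen = []
    for rec in recordings:
        if rec.subject_id not in subjects:
            continue
        eps = epoch_recording(rec, window=window, overlap=overlap)
        if (max_epochs_per_recording is not None
                and len(eps) > max_epochs_per_recording):
            idx = (rng or np.random.default_rng()).choice(
                len(eps), size=max_epochs_per_recording, replace=False)
            eps = [eps[i] for i in sorted(idx)]
        chosen.extend(eps)
    if not chosen:
        return None, None
    return stack_epochs(chosen)


def run_cv_experiment(recordings: list[WalkRecording], truth: CohortTruth,
                      model_config: ModelConfig, fold_plan: FoldPlan,
                      *, window: int = 128, overlap: float = 0.5,
                      train_epochs_per_recording: int | None = None,
                      ) -> ExperimentResult:
    """Train and evaluate the severity model under subject-wise CV.

    For each fold: train on in-sample subjects (validation subjects held
    out for early stopping), predict every epoch of every recording of the
    out-of-sample subjects, reduce per (subject, day) to the daily severity
    ŷ_d, and average each subject's observed days into one out-of-sample
    mean severity.  Aggregation across folds yields exactly one severity
    per subject, which feeds the EDSS association, the Kruskal–Wallis group
    test and the Spearman correlation with the true class index.
    """
    groups = {s.subject_id: s.group for s in truth.specs}
    class_of = {s.subject_id: s.class_index for s in truth.specs}
    edss_of = {s.subject_id: s.edss for s in truth.specs}
    covered = set(fold_plan.assignment)
    if covered != set(groups):
        raise ValueError("fold plan does not cover the cohort exactly")

    all_daily: list[DailySeverity] = []
    fold_logs = []
    for fold in range(fold_plan.k):
        test_subjects = set(fold_plan.test_subjects(fold))
        val_subjects = set(fold_plan.validation.get(fold, ()))
        train_subjects = set(fold_plan.train_subjects(fold))
        assert not (train_subjects & test_subjects), "subject leakage"
        assert not (val_subjects & test_subjects), "subject leakage"
        train_classes = {class_of[s] for s in train_subjects}
        if len(train_classes) < model_config.n_classes:
            raise ValueError(
                f"fold {fold}: training set lacks classes "
                f"{set(range(model_config.n_classes)) - train_classes}")

        sub_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(model_config.seed, fold)))
        xtr, itr = _epochs_for(recordings, train_subjects, window, overlap,
                               train_epochs_per_recording, sub_rng)
        if xtr is None:
            raise ValueError(f"fold {fold}: no training recordings")
        ytr = itr["subject_id"].map(class_of).to_numpy()
        xval, ival = _epochs_for(recordings, val_subjects, window, overlap,
                                 train_epochs_per_recording, sub_rng)
        yval = None if xval is None else ival["subject_id"].map(class_of).to_numpy()

        fold_config = ModelConfig(**{**model_config.__dict__,
                                     "seed": model_config.seed + fold})
        model = build_model(fold_config)
        log = train_model(model, xtr, ytr, val_epochs=xval, val_labels=yval,
                          config=fold_config)
        fold_logs.append(log)

        xte, ite = _epochs_for(recordings, test_subjects, window, overlap)
        if xte is None:
            logger.warning("fold %d: no test recordings", fold)
            continue
        argmax = model.forward_probs(xte).argmax(axis=1)
        ite = ite.assign(cls=argmax)
        per_day = ite.groupby(["subject_id", "study_day"])["cls"]
        for (sid, day), grp in per_day:
            all_daily.append(DailySeverity(
                subject_id=str(sid), study_day=int(day),
                value=float(grp.mean()), n_epochs=int(len(grp))))

    df = pd.DataFrame([{"subject_id": d.subject_id, "study_day": d.study_day,
                        "severity": d.value, "n_epochs": d.n_epochs}
                       for d in all_daily])
    subject = (df.groupby("subject_id")["severity"].mean().rename("severity")
               .reset_index())
    subject["group"] = subject["subject_id"].map(groups)
    subject["true_class"] = subject["subject_id"].map(class_of)
    subject["edss"] = subject["subject_id"].map(edss_of)

    ms = subject[subject["group"] != "hc"].dropna(subset=["edss"])
    association_ms = (associate_with_edss(ms["severity"], ms["edss"])
                      if len(ms) >= 3 and ms["edss"].nunique() > 1 else None)
    all_e = subject.assign(edss=subject["edss"].fillna(0.0))
    association_all = (associate_with_edss(all_e["severity"], all_e["edss"])
                       if len(all_e) >= 3 else None)

    by_group = {g: subject.loc[subject["group"] == g, "severity"].to_numpy()
                for g in GROUPS if (subject["group"] == g).any()}
    kw_h, kw_p = group_test(by_group)
    from scipy.stats import spearmanr
    rho = float(spearmanr(subject["true_class"], subject["severity"]).statistic)

    return ExperimentResult(subject_severity=subject, daily=all_daily,
                            association_ms=association_ms,
                            association_all=association_all,
                            kw_h=kw_h, kw_p=kw_p,
                            spearman_true_class=rho, fold_logs=fold_logs)
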