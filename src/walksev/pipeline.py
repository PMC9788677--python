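"""End-to-end orchestration from a single YAML configuration.

``RunConfig`` holds every knob of the pipeline (cohort composition, epoch
geometry, model hyperparameters, trend window, CV settings) with defaults
that reproduce the reference pipeline on synthetic data; every random draw
derives from its single global seed.  The three entry points mirror the
pipeline stages:

* :func:`cmd_simulate` — write a synthetic cohort to disk;
* :func:`cmd_run` — epoching → cross-validated training → daily severities
  → imputation → trends → statistics, with all artefacts written;
* :func:`cmd_trend` — impute and smooth an existing severity CSV and run
  per-subject event analyses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import longitudinal as lg
from . import simulate as sim
from .crossval import make_folds, run_cv_experiment
from .model import ModelConfig

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    n_hc: int = 24
    n_mild: int = 52
    n_mod: int = 21
    study_days: int = sim.DEFAULT_STUDY_DAYS
    sample_rate: float = sim.DEFAULT_SAMPLE_RATE
    adherence: dict = field(default_factory=lambda: {
        "hc": 0.90, "mild": 0.85, "mod": 0.80})
    relapse_specs: dict = field(default_factory=dict)
    epoch_window: int = 128
    epoch_overlap: float = 0.5
    model: ModelConfig = field(default_factory=ModelConfig)
    window_days: int = 7
    cv_folds: int = 5
    validation_fraction: float = 0.1
    train_epochs_per_recording: int | None = None
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["model"]["block_filters"] = list(self.model.block_filters)
        d["model"]["block_widths"] = list(self.model.block_widths)
        d["model"]["pool_blocks"] = list(self.model.pool_blocks)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        m = d.pop("model", {})
        for k in ("block_filters", "block_widths", "pool_blocks"):
            if k in m:
                m[k] = tuple(m[k])
        relapse = d.pop("relapse_specs", {}) or {}
        d["relapse_specs"] = {k: tuple(v) for k, v in relapse.items()}
        return cls(model=ModelConfig(**m), **d)

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


def build_truth(config: RunConfig) -> sim.CohortTruth:
    return sim.make_cohort(
        n_hc=config.n_hc, n_mild=config.n_mild, n_mod=config.n_mod,
        study_days=config.study_days, seed=config.seed,
        adherence=config.adherence,
        relapse_specs={k: tuple(v) for k, v in config.relapse_specs.items()})


def cmd_simulate(config: RunConfig, output_dir: Path | None = None) -> Path:
    """Simulate the configured cohort and write recordings + manifest +
    ground truth."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_truth(config)
    recordings = sim.simulate_cohort(truth, sample_rate=config.sample_rate)
    sim.write_cohort(truth, recordings, outdir)
    logger.info("wrote %d recordings for %d subjects to %s",
                len(recordings), len(truth.specs), outdir)
    return outdir


def cmd_run(config: RunConfig, cohort_dir: Path | None = None,
            output_dir: Path | None = None) -> dict:
    """Run the full experiment; returns (and writes) the report dict."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort_dir is not None:
        if not (Path(cohort_dir) / "manifest.json").exists():
            raise FileNotFoundError(
                f"no cohort manifest at {cohort_dir}/manifest.json")
        truth, recordings = sim.read_cohort(cohort_dir)
    else:
        truth = build_truth(config)
        recordings = sim.simulate_cohort(truth, sample_rate=config.sample_rate)

    groups = {s.subject_id: s.group for s in truth.specs}
    plan = make_folds(groups, k=config.cv_folds,
                      validation_fraction=config.validation_fraction,
                      seed=config.seed)
    result = run_cv_experiment(
        recordings, truth, config.model, plan,
        window=config.epoch_window, overlap=config.epoch_overlap,
        train_epochs_per_recording=config.train_epochs_per_recording)

    daily = pd.DataFrame(
        [{"subject_id": d.subject_id, "study_day": d.study_day,
          "value": d.value, "n_epochs": d.n_epochs, "imputed": d.imputed}
         for d in result.daily]).sort_values(["subject_id", "study_day"])
    daily.to_csv(outdir / "daily_severity.csv", index=False)
    result.subject_severity.to_csv(outdir / "subject_severity.csv", index=False)

    trends = []
    for series in lg.series_from_frame(daily):
        imp = lg.impute_pli(series)
        if len(imp.entries) >= 1:
            trends.append(lg.trend_to_frame(
                lg.moving_average(imp, config.window_days)))
    if trends:
        pd.concat(trends).to_csv(outdir / "trend.csv", index=False)

    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "n_subjects": len(truth.specs),
        "n_recordings": len(recordings),
        "fold_plan": plan.to_dict(),
        "group_medians": result.group_medians(),
        "kruskal_wallis": {"H": result.kw_h, "p": result.kw_p},
        "spearman_true_class": result.spearman_true_class,
        "association_ms_only": _assoc_dict(result.association_ms),
        "association_all_subjects": _assoc_dict(result.association_all),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    validate_report(report)
    return report


def _assoc_dict(a) -> dict | None:
    return None if a is None else dataclasses.asdict(a)


def validate_report(report: dict) -> None:
    """Schema check for the experiment report."""
    required = {"schema_version", "seed", "n_subjects", "n_recordings",
                "fold_plan", "group_medians", "kruskal_wallis",
                "spearman_true_class"}
    missing = required - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if report["schema_version"] != SCHEMA_VERSION:
        raise ValueError("unknown report schema version")


def cmd_trend(severity_csv: Path, window_days: int = 7,
              events: dict[str, list[int]] | None = None,
              output_dir: Path | None = None) -> dict:
    """Impute + smooth a severity CSV; optionally run event analyses.

    ``events`` maps subject_id to event study-days.  Writes trend.csv and
    one JSON per (subject, event); returns a summary dict.
    """
    severity_csv = Path(severity_csv)
    df = pd.read_csv(severity_csv)
    required_cols = {"subject_id", "study_day", "value"}
    if not required_cols <= set(df.columns):
        raise ValueError(
            f"{severity_csv}: expected columns {sorted(required_cols)}")
    if "imputed" not in df.columns:
        df["imputed"] = False
    outdir = Path(output_dir or severity_csv.parent)
    outdir.mkdir(parents=True, exist_ok=True)
    events = events or {}
    trends, analyses = [], []
    for series in lg.series_from_frame(df):
        imp = lg.impute_pli(series)
        if len(imp.observed().entries) < 2:
            logger.warning("subject %s has <2 observations; trend passed "
                           "through unsmoothed", series.subject_id)
            trends.append(pd.DataFrame({
                "subject_id": series.subject_id, "study_day": series.days,
                "trend": series.values, "window_days": 1}))
        else:
            trends.append(lg.trend_to_frame(
                lg.moving_average(imp, window_days)))
        for event_day in events.get(series.subject_id, []):
            analysis = lg.split_by_event(imp, event_day)
            payload = {
                "subject_id": analysis.subject_id,
                "event_day": analysis.event_day,
                "n_before": len(analysis.before),
                "n_after": len(analysis.after),
                "computable": analysis.computable,
                "reason": analysis.reason,
                "tests": (None if analysis.tests is None
                          else dataclasses.asdict(analysis.tests)),
            }
            path = outdir / f"event_{analysis.subject_id}_d{event_day}.json"
            path.write_text(json.dumps(payload, indent=2, default=float))
            analyses.append(payload)
    trend_df = pd.concat(trends)
    trend_df.to_csv(outdir / "trend.csv", index=False)
    return {"n_subjects": trend_df["subject_id"].nunique(),
            "n_events": len(analyses), "events": analyses}
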