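"""Synthetic longitudinal cohorts of smartphone two-minute-walk-test (2MWT)
accelerometry.

The generator emulates the statistical structure a remote-monitoring severity
pipeline has to cope with: three severity strata (healthy controls, mildly and
moderately disabled people with MS), one 120-second triaxial recording per
subject per study day over 24 weeks, per-subject adherence (missing days),
an arbitrary phone orientation per test, and optional relapse events that
shift gait parameters from a known date.

The gait signal model is deliberately simple — a small number of harmonics at
the step and stride frequencies with stride-to-stride frequency jitter and an
alternating left/right amplitude imbalance — chosen so that the three strata
are separable through cadence, amplitude and variability without claiming
biomechanical fidelity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

GROUPS = ("hc", "mild", "mod")

#: default device sampling rate, Hz (128 samples per 2.56 s epoch)
DEFAULT_SAMPLE_RATE = 50.0
#: 2MWT duration, seconds
TEST_DURATION_S = 120.0
#: default study length, days (24 weeks)
DEFAULT_STUDY_DAYS = 168


@dataclass(frozen=True)
class GaitParams:
    """Parameters of the harmonic gait signal model.

    step_frequency      mean step (cadence) frequency, Hz
    step_frequency_sd   stride-to-stride SD of the step frequency, Hz
    amplitude           vertical-axis dominant harmonic amplitude, g
    asymmetry           left/right amplitude imbalance, unitless in [0, 1]
    noise_sd            broadband sensor noise SD per axis, g
    """

    step_frequency: float
    step_frequency_sd: float
    amplitude: float
    asymmetry: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.step_frequency <= 0:
            raise ValueError("step_frequency must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.noise_sd < 0 or self.step_frequency_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")

    def scaled(self, freq_scale: float = 1.0, freq_sd_scale: float = 1.0,
               amplitude_scale: float = 1.0, asymmetry_shift: float = 0.0,
               ) -> "GaitParams":
        return GaitParams(
            step_frequency=self.step_frequency * freq_scale,
            step_frequency_sd=self.step_frequency_sd * freq_sd_scale,
            amplitude=self.amplitude * amplitude_scale,
            asymmetry=min(1.0, self.asymmetry + asymmetry_shift),
            noise_sd=self.noise_sd,
        )


#: Group-level default gait parameters.  Healthy controls walk fast with a
#: steady cadence; moderate MS shows slower cadence, reduced push-off
#: amplitude, higher stride-to-stride variability and stronger asymmetry —
#: the phenomenology (postural instability, gait variability, fatigue) the
#: severity classifier is meant to pick up.
DEFAULT_GROUP_PARAMS: dict[str, GaitParams] = {
    "hc": GaitParams(step_frequency=2.0, step_frequency_sd=0.03,
                     amplitude=0.35, asymmetry=0.05, noise_sd=0.05),
    "mild": GaitParams(step_frequency=1.85, step_frequency_sd=0.08,
                       amplitude=0.29, asymmetry=0.15, noise_sd=0.05),
    "mod": GaitParams(step_frequency=1.65, step_frequency_sd=0.16,
                      amplitude=0.22, asymmetry=0.30, noise_sd=0.05),
}


@dataclass(frozen=True)
class RelapseEffect:
    """Multiplicative shift applied to GaitParams during a relapse window.

    Defaults model an acute worsening (roughly one EDSS point): slower, more
    variable, weaker and more asymmetric gait.
    """

    freq_scale: float = 0.85
    freq_sd_scale: float = 2.0
    amplitude_scale: float = 0.75
    asymmetry_shift: float = 0.25


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth description of one simulated subject."""

    subject_id: str
    group: str
    baseline_params: GaitParams
    adherence: float = 0.85
    relapse_dates: tuple[int, ...] = ()
    relapse_effect: RelapseEffect = field(default_factory=RelapseEffect)
    relapse_duration: int = 21
    post_event_adherence: float | None = None
    edss: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must lie in [0, 1]")
        if self.group == "hc" and self.relapse_dates:
            raise ValueError("healthy controls cannot have relapse events")

    @property
    def class_index(self) -> int:
        return GROUPS.index(self.group)

    def params_on_day(self, study_day: int) -> GaitParams:
        """Effective gait parameters, applying any active relapse window."""
        for r in self.relapse_dates:
            if r <= study_day < r + self.relapse_duration:
                e = self.relapse_effect
                return self.baseline_params.scaled(
                    e.freq_scale, e.freq_sd_scale, e.amplitude_scale,
                    e.asymmetry_shift)
        return self.baseline_params

    def adherence_on_day(self, study_day: int) -> float:
        if (self.post_event_adherence is not None and self.relapse_dates
                and study_day >= min(self.relapse_dates)):
            return self.post_event_adherence
        return self.adherence


@dataclass(frozen=True)
class WalkRecording:
    """One 2MWT: uniformly sampled triaxial acceleration in g."""

    subject_id: str
    study_day: int
    sample_rate: float
    t: np.ndarray          # seconds, strictly increasing
    acc: np.ndarray        # (n_samples, 3) — ax, ay, az

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    def norm(self) -> np.ndarray:
        """Orientation-invariant signal magnitude ``‖a‖``."""
        return np.linalg.norm(self.acc, axis=1)


@dataclass(frozen=True)
class CohortTruth:
    """Simulator ground truth for a whole cohort."""

    specs: tuple[SubjectSpec, ...]
    seed: int
    study_days: int = DEFAULT_STUDY_DAYS

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("cohort must contain at least one subject")
        ids = [s.subject_id for s in self.specs]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for s in self.specs:
            for r in s.relapse_dates:
                if not 0 <= r < self.study_days:
                    raise ValueError(
                        f"relapse day {r} outside study span for {s.subject_id}")

    def spec_for(self, subject_id: str) -> SubjectSpec:
        for s in self.specs:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly from SO(3) via a normalized
    quaternion (components i.i.d. standard normal)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def simulate_walk(spec: SubjectSpec, study_day: int, rng_seed: int,
                  sample_rate: float = DEFAULT_SAMPLE_RATE,
                  duration: float = TEST_DURATION_S) -> WalkRecording:
    """Synthesize one 120-second 2MWT recording.

    The device-frame signal places gravity (+1 g) on the device z axis, the
    dominant step harmonic (amplitude-modulated by left/right asymmetry) and
    its second harmonic on z, a stride-frequency plus step-frequency mix on
    the antero-posterior axis, and a stride-frequency component on the
    medio-lateral axis.  Stride-to-stride cadence jitter enters through a
    piecewise-constant instantaneous frequency (one draw per step).  A single
    rotation, uniform over SO(3), is then applied to the axis triplet to
    emulate an arbitrary, fixed phone orientation for the test.

    Waveform randomness (jitter, noise) and orientation randomness come from
    independent streams spawned from ``rng_seed``, so noise-free parameter
    sets yield an identical ``‖a‖`` trace for every seed while the
    orientation still varies.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    params = spec.params_on_day(study_day)
    ss = np.random.SeedSequence(entropy=rng_seed)
    gait_rng, rot_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    f0, fsd = params.step_frequency, params.step_frequency_sd
    # one frequency draw per step; enough steps to cover the recording
    n_steps = int(np.ceil(duration * (f0 + 5 * fsd))) + 4
    if fsd > 0:
        freqs = gait_rng.normal(f0, fsd, size=n_steps)
        freqs = np.clip(freqs, 0.2 * f0, None)
    else:
        freqs = np.full(n_steps, f0)
    step_ends = np.cumsum(1.0 / freqs)             # time each step completes
    step_idx = np.searchsorted(step_ends, t, side="right")
    step_idx = np.minimum(step_idx, n_steps - 1)
    inst_f = freqs[step_idx]
    phase = 2 * np.pi * np.cumsum(inst_f) / sample_rate

    amp = params.amplitude
    # alternating step amplitude: left vs right leg push-off imbalance
    alt = np.where(step_idx % 2 == 0, 1.0 + params.asymmetry / 2,
                   1.0 - params.asymmetry / 2)
    az = 1.0 + amp * alt * np.sin(phase) + 0.25 * amp * np.sin(2 * phase)
    ay = 0.35 * amp * np.sin(phase / 2) + 0.20 * amp * np.sin(phase + np.pi / 6)
    ax = 0.25 * amp * np.sin(phase / 2 + np.pi / 3)
    acc = np.column_stack([ax, ay, az])
    if params.noise_sd > 0:
        acc = acc + gait_rng.normal(0.0, params.noise_sd, size=acc.shape)

    rot = random_rotation(rot_rng)
    acc = acc @ rot.T
    return WalkRecording(subject_id=spec.subject_id, study_day=int(study_day),
                         sample_rate=sample_rate, t=t, acc=acc)


def simulate_cohort(truth: CohortTruth,
                    sample_rate: float = DEFAULT_SAMPLE_RATE,
                    duration: float = TEST_DURATION_S,
                    ) -> list[WalkRecording]:
    """Simulate every subject over the study, dropping days by adherence.

    All randomness derives from ``truth.seed`` through per-subject spawned
    streams, so the output is bit-reproducible and independent of iteration
    order elsewhere.
    """
    root = np.random.SeedSequence(entropy=truth.seed)
    children = root.spawn(len(truth.specs))
    recordings: list[WalkRecording] = []
    for spec, child in zip(truth.specs, children):
        adh_rng = np.random.default_rng(child)
        day_seeds = child.spawn(truth.study_days)
        for day in range(truth.study_days):
            p = spec.adherence_on_day(day)
            if adh_rng.random() >= p:
                continue
            seed = int(day_seeds[day].generate_state(1)[0] % (2 ** 31))
            recordings.append(simulate_walk(spec, day, seed,
                                            sample_rate=sample_rate,
                                            duration=duration))
    return recordings


def _round_half(x: float, lo: float, hi: float) -> float:
    """Clip to [lo, hi] and round to the EDSS half-point grid."""
    return float(np.clip(np.round(x * 2) / 2, lo, hi))


def make_cohort(n_hc: int = 24, n_mild: int = 52, n_mod: int = 21,
                study_days: int = DEFAULT_STUDY_DAYS, seed: int = 0,
                adherence: dict[str, float] | None = None,
                relapse_specs: dict[str, tuple[int, ...]] | None = None,
                param_jitter: float = 0.04) -> CohortTruth:
    """Build a cohort truth with per-subject parameters jittered around the
    group defaults and per-subject EDSS drawn from the stratum distributions
    (mild 1.7 ± 0.8 on [0, 3]; moderate 4.2 ± 0.7 on [3.5, 5.5]; healthy
    controls carry no EDSS).

    ``relapse_specs`` maps subject_id to relapse study-days for subjects that
    should experience events.  ``param_jitter`` is the relative SD of the
    log-normal jitter applied to each gait parameter per subject.
    """
    if n_hc + n_mild + n_mod <= 0:
        raise ValueError("cohort must contain at least one subject")
    adherence = adherence or {"hc": 0.90, "mild": 0.85, "mod": 0.80}
    relapse_specs = relapse_specs or {}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    specs: list[SubjectSpec] = []
    counts = {"hc": n_hc, "mild": n_mild, "mod": n_mod}
    edss_dist = {"mild": (1.7, 0.8, 0.0, 3.0), "mod": (4.2, 0.7, 3.5, 5.5)}
    for group in GROUPS:
        base = DEFAULT_GROUP_PARAMS[group]
        for i in range(counts[group]):
            sid = f"{group}{i:03d}"
            jit = np.exp(rng.normal(0.0, param_jitter, size=4))
            params = GaitParams(
                step_frequency=base.step_frequency * jit[0],
                step_frequency_sd=base.step_frequency_sd * jit[1],
                amplitude=base.amplitude * jit[2],
                asymmetry=min(1.0, base.asymmetry * jit[3]),
                noise_sd=base.noise_sd,
            )
            if group in edss_dist:
                mu, sd, lo, hi = edss_dist[group]
                edss = _round_half(rng.normal(mu, sd), lo, hi)
            else:
                edss = None
            specs.append(SubjectSpec(
                subject_id=sid, group=group, baseline_params=params,
                adherence=adherence[group],
                relapse_dates=tuple(relapse_specs.get(sid, ())),
                edss=edss))
    return CohortTruth(specs=tuple(specs), seed=seed, study_days=study_days)


def cadence_cv(rec: WalkRecording, min_step_interval_s: float = 0.3) -> float:
    """Cadence-variability summary: coefficient of variation of step
    intervals estimated by peak-picking on the mean-removed ``‖a‖`` signal.

    This is the class-separability statistic: with default group parameters
    its group means order hc < mild < mod.
    """
    sig = rec.norm()
    sig = sig - sig.mean()
    distance = max(1, int(min_step_interval_s * rec.sample_rate))
    peaks, _ = find_peaks(sig, distance=distance, height=0.0)
    if len(peaks) < 3:
        return float("nan")
    intervals = np.diff(peaks) / rec.sample_rate
    return float(np.std(intervals) / np.mean(intervals))


# ---------------------------------------------------------------------------
# on-disk formats

def recording_filename(subject_id: str, study_day: int) -> str:
    return f"{subject_id}_d{study_day:03d}.csv"


def write_recording_csv(rec: WalkRecording, directory: Path) -> Path:
    path = Path(directory) / recording_filename(rec.subject_id, rec.study_day)
    df = pd.DataFrame({"t": rec.t, "ax": rec.acc[:, 0],
                       "ay": rec.acc[:, 1], "az": rec.acc[:, 2]})
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_recording_csv(path: Path, subject_id: str | None = None,
                       study_day: int | None = None) -> WalkRecording:
    path = Path(path)
    if subject_id is None or study_day is None:
        stem = path.stem
        sid, _, day = stem.rpartition("_d")
        subject_id = subject_id or sid
        study_day = study_day if study_day is not None else int(day)
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    dt = np.diff(t)
    if len(dt) and not np.all(dt > 0):
        raise ValueError(f"non-increasing timestamps in {path}")
    sample_rate = 1.0 / float(np.median(dt)) if len(dt) else DEFAULT_SAMPLE_RATE
    return WalkRecording(subject_id=subject_id, study_day=int(study_day),
                         sample_rate=round(sample_rate, 6), t=t,
                         acc=df[["ax", "ay", "az"]].to_numpy())


def write_cohort(truth: CohortTruth, recordings: list[WalkRecording],
                 directory: Path) -> None:
    """Write recording CSVs plus the manifest JSON and ground-truth CSV."""
    directory = Path(directory)
    rec_dir = directory / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording_csv(rec, rec_dir)
    manifest = {
        "seed": truth.seed,
        "study_days": truth.study_days,
        "subjects": [_spec_to_dict(s) for s in truth.specs],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    rows = [{"subject_id": s.subject_id, "group": s.group,
             "edss": s.edss,
             "adherence": s.adherence,
             "relapse_dates": ";".join(map(str, s.relapse_dates))}
            for s in truth.specs]
    pd.DataFrame(rows).to_csv(directory / "truth.csv", index=False)


def _spec_to_dict(s: SubjectSpec) -> dict:
    d = dataclasses.asdict(s)
    d["relapse_dates"] = list(s.relapse_dates)
    return d


def _spec_from_dict(d: dict) -> SubjectSpec:
    d = dict(d)
    d["baseline_params"] = GaitParams(**d["baseline_params"])
    d["relapse_effect"] = RelapseEffect(**d["relapse_effect"])
    d["relapse_dates"] = tuple(d["relapse_dates"])
    return SubjectSpec(**d)


def read_cohort(directory: Path) -> tuple[CohortTruth, list[WalkRecording]]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    specs = tuple(_spec_from_dict(d) for d in manifest["subjects"])
    truth = CohortTruth(specs=specs, seed=manifest["seed"],
                        study_days=manifest["study_days"])
    recordings = [read_recording_csv(p)
                  for p in sorted((directory / "recordings").glob("*.csv"))]
    return truth, recordings
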