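"""Sliding-window epoching of walk recordings and rotation augmentation.

A recording is partitioned into overlapping epochs of 128 samples (2.56 s at
50 Hz) with 50% overlap.  Each epoch is a 128 x 4 tensor whose channels are
the three acceleration axes plus the orientation-invariant magnitude ``‖a‖``.
Training-time augmentation rotates the axis triplet by a random rotation
(uniform over SO(3)); the magnitude channel is invariant under it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import WalkRecording, random_rotation

logger = logging.getLogger(__name__)

EPOCH_SAMPLES = 128
EPOCH_OVERLAP = 0.5
N_CHANNELS = 4


@dataclass(frozen=True)
class EpochTensor:
    """One model-ready window: ``values`` is (window, 4) with channels
    (ax, ay, az, ‖a‖)."""

    values: np.ndarray
    subject_id: str
    study_day: int
    epoch_index: int

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(
                f"epoch values must be (window, {N_CHANNELS}); "
                f"got {self.values.shape}")


def epoch_count(n_samples: int, window: int, step: int) -> int:
    """Number of full windows: floor((L - window)/step) + 1, or 0 if short."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def epoch_recording(rec: WalkRecording, window: int = EPOCH_SAMPLES,
                    overlap: float = EPOCH_OVERLAP) -> list[EpochTensor]:
    """Partition a recording into overlapping epochs.

    Epochs start every ``window * (1 - overlap)`` samples; a trailing partial
    window is discarded.  A recording shorter than one window yields an empty
    list (logged at warning level).
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    step = int(round(window * (1.0 - overlap)))
    if step < 1:
        raise ValueError("window*(1-overlap) must be at least one sample")
    L = rec.n_samples
    if L < window:
        logger.warning("recording %s day %d: %d samples < window %d; skipped",
                       rec.subject_id, rec.study_day, L, window)
        return []
    norm = rec.norm()
    out = []
    for i in range(epoch_count(L, window, step)):
        s = i * step
        vals = np.empty((window, N_CHANNELS))
        vals[:, :3] = rec.acc[s:s + window]
        vals[:, 3] = norm[s:s + window]
        out.append(EpochTensor(values=vals, subject_id=rec.subject_id,
                               study_day=rec.study_day, epoch_index=i))
    return out


def augment_rotation(epoch: EpochTensor, rng_seed: int) -> EpochTensor:
    """Rotate the axis channels by one random rotation (uniform over SO(3))
    and recompute the magnitude channel.  Training-time only."""
    rng = np.random.default_rng(rng_seed)
    rot = random_rotation(rng)
    vals = epoch.values.copy()
    vals[:, :3] = vals[:, :3] @ rot.T
    vals[:, 3] = np.linalg.norm(vals[:, :3], axis=1)
    return replace(epoch, values=vals)


# ---------------------------------------------------------------------------
# batch containers — the model consumes stacked arrays, not python lists

def stack_epochs(epochs: list[EpochTensor]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack epochs into an (N, window, 4) float32 array plus an index table
    (subject_id, study_day, epoch_index) aligned with axis 0."""
    if not epochs:
        raise ValueError("no epochs to stack")
    arr = np.stack([e.values for e in epochs]).astype(np.float32)
    index = pd.DataFrame({
        "subject_id": [e.subject_id for e in epochs],
        "study_day": [e.study_day for e in epochs],
        "epoch_index": [e.epoch_index for e in epochs],
    })
    return arr, index


def rotate_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply an independent random rotation to every epoch of a stacked
    batch (N, window, 4), recomputing the magnitude channel.  Vectorised
    equivalent of per-epoch :func:`augment_rotation`."""
    q = rng.standard_normal((x.shape[0], 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, i, j, k = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    rots = np.empty((x.shape[0], 3, 3))
    rots[:, 0, 0] = 1 - 2 * (j * j + k * k)
    rots[:, 0, 1] = 2 * (i * j - w * k)
    rots[:, 0, 2] = 2 * (i * k + w * j)
    rots[:, 1, 0] = 2 * (i * j + w * k)
    rots[:, 1, 1] = 1 - 2 * (i * i + k * k)
    rots[:, 1, 2] = 2 * (j * k - w * i)
    rots[:, 2, 0] = 2 * (i * k - w * j)
    rots[:, 2, 1] = 2 * (j * k + w * i)
    rots[:, 2, 2] = 1 - 2 * (i * i + j * j)
    out = x.copy()
    out[:, :, :3] = np.einsum("nwc,nrc->nwr", x[:, :, :3].astype(np.float64),
                              rots).astype(x.dtype)
    out[:, :, 3] = np.linalg.norm(out[:, :, :3], axis=2)
    return out


def save_epoch_store(path_prefix, arr: np.ndarray, index: pd.DataFrame) -> None:
    """Persist a stacked epoch array (.npy) with its CSV index table."""
    np.save(str(path_prefix) + "_epochs.npy", arr)
    index.to_csv(str(path_prefix) + "_index.csv", index=False)


def load_epoch_store(path_prefix) -> tuple[np.ndarray, pd.DataFrame]:
    arr = np.load(str(path_prefix) + "_epochs.npy")
    index = pd.read_csv(str(path_prefix) + "_index.csv")
    return arr, index
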