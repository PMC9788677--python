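"""The causal 1-D deep convolutional severity classifier and the reduction
of epoch predictions to a continuous daily severity.

The network classifies each 128-sample, 4-channel epoch as coming from a
healthy control (class 0), a mildly (1) or a moderately (2) disabled walker.
Architecture: four causal convolutional blocks with batch normalisation
(conv 32x9 with l2 on its kernel; conv 64x3 + maxpool(2,2); conv 64x3;
conv 128x6 + maxpool(2,2)), then a dense softmax over the three classes,
trained with categorical cross-entropy under Adam.

The daily severity ŷ_d is the mean of the per-epoch argmax classes over one
test day — a continuous value in [0, 2] interpolating healthy → mild →
moderate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .epoching import EpochTensor, rotate_batch, stack_epochs

logger = logging.getLogger(__name__)

CLASS_NAMES = ("hc", "mild", "mod")
N_CLASSES = 3


@dataclass
class ModelConfig:
    """Hyperparameters of the severity network.

    Architecture and optimiser defaults are the reference settings of the
    severity pipeline; training length, batch size and patience default to
    values suitable for small synthetic cohorts and are freely configurable.
    ``learning_rate`` defaults to the fine-tuning rate 1e-5; when training
    from scratch on synthetic data a larger rate (e.g. 1e-3) converges within
    a practical number of passes.
    """

    input_samples: int = 128
    input_channels: int = 4
    block_filters: tuple[int, ...] = (32, 64, 64, 128)
    block_widths: tuple[int, ...] = (9, 3, 3, 6)
    pool_blocks: tuple[int, ...] = (1, 3)      # 0-based blocks with maxpool
    pool_size: int = 2
    pool_stride: int = 2
    l2_block1: float = 1e-3
    bn_momentum: float = 0.99
    bn_eps: float = 1e-2
    n_classes: int = N_CLASSES
    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    train_epochs: int = 50
    batch_size: int = 64
    patience: int = 10
    augment: bool = True
    freeze_block1: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for k in ("block_filters", "block_widths", "pool_blocks"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class EpochPrediction:
    """Class posterior for one epoch; argmax ties break toward the lower
    (less severe) class index."""

    probs: np.ndarray
    argmax_class: int
    subject_id: str
    study_day: int
    epoch_index: int


@dataclass(frozen=True)
class DailySeverity:
    """Continuous severity ŷ_d for one (subject, test day)."""

    subject_id: str
    study_day: int
    value: float
    n_epochs: int
    imputed: bool = False


@dataclass
class TrainingLog:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    stopped_early: bool = False


class SeverityDCNN:
    """Model handle wrapping the NumPy network; built by :func:`build_model`."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
        layers: list[nn.Layer] = []
        c_in = config.input_channels
        length = config.input_samples
        for b, (f, w) in enumerate(zip(config.block_filters,
                                       config.block_widths)):
            l2 = config.l2_block1 if b == 0 else 0.0
            layers.append(nn.CausalConv1D(c_in, f, w, l2=l2, rng=rng))
            layers.append(nn.BatchNorm1D(f, momentum=config.bn_momentum,
                                         eps=config.bn_eps))
            layers.append(nn.ReLU())
            if b in config.pool_blocks:
                layers.append(nn.MaxPool1D(config.pool_size,
                                           config.pool_stride))
                length //= config.pool_stride
            c_in = f
        layers.append(nn.Flatten())
        layers.append(nn.Dense(length * c_in, config.n_classes, rng=rng))
        self.net = nn.Sequential(layers)
        self.trained = False

    # -- geometry -----------------------------------------------------------
    def _check_geometry(self, x: np.ndarray) -> None:
        expected = (self.config.input_samples, self.config.input_channels)
        if x.ndim != 3 or x.shape[1:] != expected:
            raise ValueError(
                f"model expects input of shape (batch, {expected[0]}, "
                f"{expected[1]}); got {x.shape}")

    @property
    def first_kernel_shape(self) -> tuple[int, int, int]:
        for layer in self.net.layers:
            if isinstance(layer, nn.CausalConv1D):
                return layer.kernel.shape
        raise RuntimeError("no conv layer")

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    # -- inference ----------------------------------------------------------
    def forward_probs(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class posteriors for a stacked batch; inference mode (BN frozen),
        no augmentation."""
        self._check_geometry(x)
        out = np.empty((x.shape[0], self.config.n_classes), dtype=np.float64)
        for s in range(0, x.shape[0], batch_size):
            logits = self.net.forward(x[s:s + batch_size].astype(np.float32),
                                      training=False)
            out[s:s + batch_size] = nn.softmax(logits.astype(np.float64))
        return out

    # -- persistence --------------------------------------------------------
    def save(self, path_prefix: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar with the configuration."""
        arrays = {}
        for i, layer in enumerate(self.net.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_param{j}"] = p
            if isinstance(layer, nn.BatchNorm1D):
                arrays[f"layer{i}_running_mean"] = layer.running_mean
                arrays[f"layer{i}_running_var"] = layer.running_var
        np.savez(str(path_prefix) + "_weights.npz", **arrays)
        Path(str(path_prefix) + "_config.json").write_text(self.config.to_json())

    def load_weights(self, path_prefix: str | Path) -> None:
        """Weight-injection hook: also usable to start from pre-trained
        weights instead of random initialisation."""
        data = np.load(str(path_prefix) + "_weights.npz")
        for i, layer in enumerate(self.net.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = data[f"layer{i}_param{j}"]
            if isinstance(layer, nn.BatchNorm1D):
                layer.running_mean = data[f"layer{i}_running_mean"]
                layer.running_var = data[f"layer{i}_running_var"]
        self.trained = True

    @classmethod
    def from_checkpoint(cls, path_prefix: str | Path) -> "SeverityDCNN":
        config = ModelConfig.from_json(
            Path(str(path_prefix) + "_config.json").read_text())
        model = cls(config)
        model.load_weights(path_prefix)
        return model


def build_model(config: ModelConfig | None = None) -> SeverityDCNN:
    """Construct the severity network from its configuration."""
    return SeverityDCNN(config or ModelConfig())


def _as_batch(epochs, labels=None):
    if isinstance(epochs, np.ndarray):
        x = epochs.astype(np.float32)
        index = None
    else:
        x, index = stack_epochs(list(epochs))
    y = None if labels is None else np.asarray(labels, dtype=np.int64)
    return x, y, index


def train_model(model: SeverityDCNN, epochs, labels, *,
                val_epochs=None, val_labels=None,
                config: ModelConfig | None = None) -> TrainingLog:
    """Train the classifier on labelled epochs.

    ``epochs`` may be a list of :class:`EpochTensor` or a stacked
    (N, 128, 4) array; ``labels`` are the subjects' group class indices.
    Rotation augmentation (a fresh random rotation per epoch per pass) is
    applied to training batches only.  Early stopping monitors validation
    loss when a validation set is supplied.
    """
    config = config or model.config
    x, y, _ = _as_batch(epochs, labels)
    model._check_geometry(x)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    xv = yv = None
    if val_epochs is not None:
        xv, yv, _ = _as_batch(val_epochs, val_labels)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    params = model.net.parameters()
    grads = model.net.gradients()
    if config.freeze_block1:
        conv1 = next(l for l in model.net.layers
                     if isinstance(l, nn.CausalConv1D))
        keep = [i for i, p in enumerate(params)
                if not any(p is q for q in conv1.params)]
        params = [params[i] for i in keep]
        grads = [grads[i] for i in keep]
    opt = nn.Adam(params, lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)

    log = TrainingLog()
    best_val = np.inf
    best_state = None
    stale = 0
    n = x.shape[0]
    for epoch_i in range(config.train_epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        total_correct = 0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb = x[idx]
            if config.augment:
                xb = rotate_batch(xb, rng)
            logits = model.net.forward(xb, training=True)
            probs = nn.softmax(logits.astype(np.float64))
            loss = nn.cross_entropy(probs, y[idx]) + model.net.l2_loss()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at pass {epoch_i}; aborting training")
            model.net.backward(nn.cross_entropy_grad(probs, y[idx]))
            opt.step(grads)
            total_loss += loss * len(idx)
            total_correct += int((probs.argmax(axis=1) == y[idx]).sum())
        log.loss.append(total_loss / n)
        log.accuracy.append(total_correct / n)
        msg = f"pass {epoch_i}: loss={log.loss[-1]:.4f} acc={log.accuracy[-1]:.3f}"
        if xv is not None and len(xv):
            pv = model.forward_probs(xv)
            vl = nn.cross_entropy(pv, yv)
            log.val_loss.append(vl)
            log.val_accuracy.append(float((pv.argmax(axis=1) == yv).mean()))
            msg += f" val_loss={vl:.4f} val_acc={log.val_accuracy[-1]:.3f}"
            if vl < best_val - 1e-6:
                best_val = vl
                best_state = [p.copy() for p in model.net.parameters()]
                stale = 0
            else:
                stale += 1
                if stale > config.patience:
                    log.stopped_early = True
                    logger.info("early stopping at pass %d", epoch_i)
                    break
        logger.debug(msg)
    if best_state is not None:
        for p, bp in zip(model.net.parameters(), best_state):
            p[...] = bp
    _recalibrate_bn(model, x, batch_size=config.batch_size)
    model.trained = True
    return log


def _recalibrate_bn(model: SeverityDCNN, x: np.ndarray,
                    batch_size: int = 256, max_samples: int = 4096) -> None:
    """Replace BN running statistics with population statistics of the
    training set under the final weights.

    With short training runs the momentum-0.99 exponential average is still
    dominated by its initial values, which mis-calibrates inference mode;
    one exact pass over (a sample of) the training data removes that
    dependence on training length.
    """
    bns = [l for l in model.net.layers if isinstance(l, nn.BatchNorm1D)]
    if not bns:
        return
    if x.shape[0] > max_samples:
        sel = np.random.default_rng(0).choice(x.shape[0], size=max_samples,
                                              replace=False)
        x = x[sel]
    sums = [None] * len(bns)
    sqsums = [None] * len(bns)
    counts = [0] * len(bns)

    captured: list[np.ndarray] = []
    for s in range(0, x.shape[0], batch_size):
        xb = x[s:s + batch_size].astype(np.float32)
        h = xb
        bi = 0
        for layer in model.net.layers:
            if isinstance(layer, nn.BatchNorm1D):
                m = h.mean(axis=(0, 1), dtype=np.float64)
                sq = (h.astype(np.float64) ** 2).mean(axis=(0, 1))
                n = h.shape[0] * h.shape[1]
                sums[bi] = m * n if sums[bi] is None else sums[bi] + m * n
                sqsums[bi] = sq * n if sqsums[bi] is None else sqsums[bi] + sq * n
                counts[bi] += n
                # batch-normalise with batch stats so downstream activations
                # match what training-mode forward produced
                h = layer.forward(h, training=True)
                bi += 1
            else:
                h = layer.forward(h, training=False)
    for layer, s_, sq_, n_ in zip(bns, sums, sqsums, counts):
        mean = s_ / n_
        var = sq_ / n_ - mean ** 2
        layer.running_mean = mean.astype(np.float32)
        layer.running_var = np.maximum(var, 0).astype(np.float32)


def predict_epochs(model: SeverityDCNN, epochs) -> list[EpochPrediction]:
    """Posterior class probabilities per epoch; deterministic inference
    (BN frozen, no augmentation).  Argmax ties break toward the lower class
    index."""
    epochs = list(epochs)
    x, _, index = _as_batch(epochs)
    probs = model.forward_probs(x)
    out = []
    for e, p in zip(epochs, probs):
        out.append(EpochPrediction(
            probs=p, argmax_class=int(np.argmax(p)),  # first max = lower class
            subject_id=e.subject_id, study_day=e.study_day,
            epoch_index=e.epoch_index))
    return out


def predict_batch(model: SeverityDCNN, x: np.ndarray) -> np.ndarray:
    """Argmax classes for a stacked batch (fast path used by the CV loop)."""
    return model.forward_probs(x).argmax(axis=1)


def daily_severity(preds: list[EpochPrediction]) -> DailySeverity:
    """ŷ_d: the mean of per-epoch argmax classes over one test day.

    The mean is over hard argmax labels, not over posterior probabilities,
    so ŷ_d reaches an endpoint only when every epoch agrees.
    """
    if not preds:
        raise ValueError("no epoch predictions for this day — the day is "
                         "missing, not zero-severity")
    keys = {(p.subject_id, p.study_day) for p in preds}
    if len(keys) != 1:
        raise ValueError(f"predictions span multiple (subject, day): {keys}")
    (sid, day), = keys
    value = float(np.mean([p.argmax_class for p in preds]))
    return DailySeverity(subject_id=sid, study_day=day, value=value,
                         n_epochs=len(preds))


def subject_mean_severity(series, include_imputed: bool = False) -> float:
    """Mean daily severity for one subject over non-imputed days (imputed
    values enter trend estimation only, never model evaluation)."""
    vals = [s.value for s in series if include_imputed or not s.imputed]
    if not vals:
        raise ValueError("no observed (non-imputed) days in series")
    return float(np.mean(vals))
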