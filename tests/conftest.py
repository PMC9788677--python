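"""Shared fixtures.

The expensive fixture is a severity classifier trained once per session on a
small, well-separated synthetic cohort; several tests (prediction
determinism, parameter recovery, event sensitivity) reuse it instead of
retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from walksev import simulate as sim
from walksev.epoching import epoch_recording, stack_epochs
from walksev.model import ModelConfig, build_model, train_model


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects (4 per class), 6 study days, default group parameters."""
    truth = sim.make_cohort(n_hc=4, n_mild=4, n_mod=4, study_days=6, seed=21)
    recordings = sim.simulate_cohort(truth)
    return truth, recordings


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    """A classifier trained from scratch on the small cohort (8 epochs per
    recording, 12 passes, lr 1e-3) together with its training log."""
    truth, recordings = small_cohort
    class_of = {s.subject_id: s.class_index for s in truth.specs}
    rng = np.random.default_rng(5)
    epochs = []
    for rec in recordings:
        es = epoch_recording(rec)
        idx = rng.choice(len(es), size=8, replace=False)
        epochs.extend(es[i] for i in sorted(idx))
    x, index = stack_epochs(epochs)
    y = index["subject_id"].map(class_of).to_numpy()
    config = ModelConfig(train_epochs=12, batch_size=64, learning_rate=1e-3,
                         seed=5)
    model = build_model(config)
    log = train_model(model, x, y, config=config)
    return model, log


@pytest.fixture(scope="session")
def reference_model():
    """The canonical reference scorer used by the event-sensitivity
    experiment (see walksev.experiments.train_reference_model)."""
    from walksev.experiments import train_reference_model
    return train_reference_model(seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
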