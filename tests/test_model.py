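"""Severity network geometry, training sanity, prediction determinism, and
the daily-severity reduction (mean of per-epoch argmax classes)."""

import itertools

import numpy as np
import pytest

from walksev.model import (DailySeverity, EpochPrediction, ModelConfig,
                           build_model, daily_severity, predict_epochs,
                           subject_mean_severity, train_model)
from walksev.epoching import EpochTensor


def _pred(cls, probs=None, sid="s", day=0, idx=0):
    if probs is None:
        probs = np.full(3, 0.1)
        probs[cls] = 0.8
    return EpochPrediction(probs=np.asarray(probs), argmax_class=cls,
                           subject_id=sid, study_day=day, epoch_index=idx)


def _epochs(x):
    return [EpochTensor(v.astype(np.float64), "s", 0, i)
            for i, v in enumerate(x)]


class TestArchitecture:
    def test_first_kernel_shape_and_output(self):
        m = build_model(ModelConfig(seed=0))
        assert m.first_kernel_shape == (9, 4, 32)
        probs = m.forward_probs(np.zeros((2, 128, 4), dtype=np.float32))
        assert probs.shape == (2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(np.isfinite(probs))      # constant-zero input is valid

    def test_parameter_count_deterministic(self):
        a = build_model(ModelConfig(seed=1))
        b = build_model(ModelConfig(seed=2))
        assert a.n_parameters() == b.n_parameters() == 81891

    def test_wrong_geometry_raises(self):
        m = build_model()
        with pytest.raises(ValueError, match="128"):
            m.forward_probs(np.zeros((2, 64, 4), dtype=np.float32))
        with pytest.raises(ValueError):
            m.forward_probs(np.zeros((2, 128, 3), dtype=np.float32))

    def test_causality_of_untrained_conv_stack(self):
        """Output at epoch position t must not depend on future samples:
        perturbing the last sample leaves all pre-pool conv features at
        earlier positions unchanged."""
        from walksev import nn
        rng = np.random.default_rng(0)
        conv = nn.CausalConv1D(4, 8, 9, rng=rng)
        x = rng.standard_normal((1, 128, 4)).astype(np.float32)
        y1 = conv.forward(x, training=False)
        x2 = x.copy()
        x2[0, -1, :] += 10
        y2 = conv.forward(x2, training=False)
        np.testing.assert_array_equal(y1[0, :-1], y2[0, :-1])
        assert np.abs(y1[0, -1] - y2[0, -1]).max() > 0


class TestTraining:
    def test_loss_decreases_on_separable_toy(self, rng):
        x = rng.standard_normal((180, 128, 4)).astype(np.float32) * 0.05
        y = np.repeat([0, 1, 2], 60)
        t = np.arange(128) / 50.0
        for i in range(180):
            f = [2.0, 1.7, 1.4][y[i]]
            x[i, :, 2] += np.sin(2 * np.pi * f * t)
            x[i, :, 3] = np.linalg.norm(x[i, :, :3], axis=1)
        cfg = ModelConfig(train_epochs=8, batch_size=32, learning_rate=1e-3,
                          seed=11)
        m = build_model(cfg)
        log = train_model(m, x, y, config=cfg)
        assert log.loss[-1] < log.loss[0]
        assert log.accuracy[-1] > 0.8

    def test_shuffled_labels_give_chance_level_holdout(self, small_cohort):
        """Permutation null: training on randomly shuffled labels yields
        held-out epoch accuracy within 10 points of 1/3 over 5 seeds."""
        from walksev.epoching import epoch_recording, stack_epochs
        truth, recordings = small_cohort
        holdout = {"hc003", "mild003", "mod003"}
        tr, te = [], []
        for rec in recordings:
            es = epoch_recording(rec)[:4]
            (te if rec.subject_id in holdout else tr).extend(es)
        xtr, _ = stack_epochs(tr)
        xte, ite = stack_epochs(te)
        class_of = {s.subject_id: s.class_index for s in truth.specs}
        yte = ite["subject_id"].map(class_of).to_numpy()
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ytr = rng.integers(0, 3, len(xtr))
            if len(np.unique(ytr)) < 2:
                continue
            cfg = ModelConfig(train_epochs=4, batch_size=64,
                              learning_rate=1e-3, seed=seed)
            m = build_model(cfg)
            train_model(m, xtr, ytr, config=cfg)
            accs.append(float((m.forward_probs(xte).argmax(1) == yte).mean()))
        assert abs(np.mean(accs) - 1 / 3) <= 0.10

    def test_noise_free_classes_fully_learnable(self):
        """With noise_sd -> 0 the strata are separable by construction:
        a nearest-centroid oracle on spectral features exceeds 0.9 held-out
        accuracy, and so does the trained network."""
        from walksev import simulate as sim
        from walksev.epoching import epoch_recording, stack_epochs

        specs, recs = [], []
        for gi, group in enumerate(sim.GROUPS):
            p = sim.DEFAULT_GROUP_PARAMS[group]
            quiet = sim.GaitParams(p.step_frequency, p.step_frequency_sd,
                                   p.amplitude, p.asymmetry, noise_sd=1e-6)
            for i in range(4):
                spec = sim.SubjectSpec(f"{group}{i}", group, quiet)
                specs.append(spec)
                for day in range(3):
                    recs.append(sim.simulate_walk(spec, day,
                                                  7000 + 100 * gi + i * 3 + day))
        class_of = {s.subject_id: s.class_index for s in specs}
        holdout = {f"{g}3" for g in sim.GROUPS}
        tr, te = [], []
        for rec in recs:
            es = epoch_recording(rec)[::6]         # 16 epochs per recording
            (te if rec.subject_id in holdout else tr).extend(es)
        xtr, itr = stack_epochs(tr)
        xte, ite = stack_epochs(te)
        ytr = itr["subject_id"].map(class_of).to_numpy()
        yte = ite["subject_id"].map(class_of).to_numpy()

        # oracle: nearest centroid on the magnitude-channel power spectrum
        def feats(x):
            spec = np.abs(np.fft.rfft(x[:, :, 3] - x[:, :, 3].mean(
                axis=1, keepdims=True), axis=1))
            return spec / np.linalg.norm(spec, axis=1, keepdims=True)
        ftr, fte = feats(xtr), feats(xte)
        centroids = np.stack([ftr[ytr == k].mean(axis=0) for k in range(3)])
        oracle = np.linalg.norm(fte[:, None, :] - centroids[None], axis=2
                                ).argmin(axis=1)
        assert (oracle == yte).mean() > 0.9

        cfg = ModelConfig(train_epochs=25, batch_size=64,
                          learning_rate=1e-3, seed=2)
        m = build_model(cfg)
        train_model(m, xtr, ytr, config=cfg)
        assert (m.forward_probs(xte).argmax(1) == yte).mean() > 0.9

    def test_single_class_training_raises(self, rng):
        x = rng.standard_normal((20, 128, 4)).astype(np.float32)
        m = build_model()
        with pytest.raises(ValueError, match="two classes"):
            train_model(m, x, np.zeros(20, dtype=int))


class TestPrediction:
    def test_deterministic_and_duplicated(self, trained_model, rng):
        model, _ = trained_model
        x = rng.standard_normal((10, 128, 4)).astype(np.float32)
        eps = _epochs(x) + _epochs(x)
        preds = predict_epochs(model, eps)
        for a, b in zip(preds[:10], preds[10:]):
            np.testing.assert_array_equal(a.probs, b.probs)
            assert a.argmax_class == b.argmax_class
        # a separate call over a different batch composition may differ only
        # by float32 GEMM blocking; 1e-7 is the documented tolerance
        p2 = model.forward_probs(x)
        np.testing.assert_allclose(np.stack([p.probs for p in preds[:10]]),
                                   p2, atol=1e-7)

    def test_probs_sum_to_one(self, trained_model, rng):
        model, _ = trained_model
        preds = predict_epochs(model,
                               _epochs(rng.standard_normal((30, 128, 4))))
        for p in preds:
            assert abs(p.probs.sum() - 1.0) < 1e-6
            assert np.all(p.probs >= 0)

    def test_argmax_tie_breaks_to_lower_class(self):
        # np.argmax returns the first maximum; the contract is explicit
        assert int(np.argmax(np.array([0.4, 0.4, 0.2]))) == 0
        assert int(np.argmax(np.array([0.2, 0.4, 0.4]))) == 1


class TestDailySeverity:
    @pytest.mark.parametrize("classes,expected", [
        ((0, 0, 0, 0), 0.0),
        ((2, 2, 1, 1), 1.5),
        ((0, 1, 2), 1.0),
        ((2, 2, 2), 2.0),
    ])
    def test_hand_examples(self, classes, expected):
        d = daily_severity([_pred(c, idx=i) for i, c in enumerate(classes)])
        assert d.value == pytest.approx(expected)
        assert d.n_epochs == len(classes)

    def test_exhaustive_multisets_match_brute_force_mean(self):
        """Every multiset of size <= 6 over {0,1,2} against the brute-force
        mean oracle; also order-invariance and range bounds."""
        for n in range(1, 7):
            for combo in itertools.combinations_with_replacement((0, 1, 2), n):
                expected = sum(combo) / n          # brute-force mean
                got = daily_severity(
                    [_pred(c, idx=i) for i, c in enumerate(combo)])
                assert got.value == pytest.approx(expected)
                assert 0.0 <= got.value <= 2.0
                shuffled = list(combo)[::-1]
                got2 = daily_severity(
                    [_pred(c, idx=i) for i, c in enumerate(shuffled)])
                assert got2.value == got.value
                # endpoint 2 reached iff every epoch argmax is 2
                assert (got.value == 2.0) == all(c == 2 for c in combo)

    def test_empty_day_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            daily_severity([])

    def test_mixed_days_rejected(self):
        with pytest.raises(ValueError):
            daily_severity([_pred(0, day=1), _pred(1, day=2)])


class TestSubjectMean:
    def test_mean_over_observed_days(self):
        days = [DailySeverity("s", 0, 0.0, 4), DailySeverity("s", 1, 2.0, 4)]
        assert subject_mean_severity(days) == pytest.approx(1.0)
        assert subject_mean_severity([DailySeverity("s", 0, 1.5, 4)]) == 1.5

    def test_imputed_days_excluded(self):
        days = [DailySeverity("s", 0, 1.0, 4),
                DailySeverity("s", 1, 2.0, 0, imputed=True)]
        assert subject_mean_severity(days) == pytest.approx(1.0)
        assert subject_mean_severity(days, include_imputed=True) == \
            pytest.approx(1.5)

    def test_all_imputed_raises(self):
        with pytest.raises(ValueError):
            subject_mean_severity([DailySeverity("s", 0, 1.0, 0,
                                                 imputed=True)])


class TestPersistence:
    def test_checkpoint_round_trip(self, trained_model, tmp_path, rng):
        model, _ = trained_model
        x = rng.standard_normal((5, 128, 4)).astype(np.float32)
        before = model.forward_probs(x)
        prefix = tmp_path / "ckpt"
        model.save(prefix)
        from walksev.model import SeverityDCNN
        reloaded = SeverityDCNN.from_checkpoint(prefix)
        np.testing.assert_array_equal(reloaded.forward_probs(x), before)
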