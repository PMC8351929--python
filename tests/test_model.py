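import numpy as np
import pytest

from gaitevents import (
    ContactModel,
    LSTMCellParams,
    LSTMState,
    ModelConfig,
    PaddedBatch,
    Scaler,
    lstm_cell_step,
)
from gaitevents.model import cross_validate, masked_accuracy, masked_bce, train
from gaitevents.cycles import FeatureSequence, GaitCycle, ContactLabelSequence, standardise_and_pad
from oracles import scalar_cell_step


def random_params(rng, hsz, d):
    return LSTMCellParams(
        gate_weights=rng.normal(scale=0.5, size=(3 * hsz, hsz + d)),
        gate_bias=rng.normal(scale=0.5, size=3 * hsz),
        cell_weights=rng.normal(scale=0.5, size=(hsz, hsz + d)),
        cell_bias=rng.normal(scale=0.5, size=hsz),
    )


class TestLSTMCell:
    def test_all_zero_weights_give_half_gates_and_zero_states(self):
        p = LSTMCellParams(np.zeros((9, 5)), np.zeros(9), np.zeros((3, 5)), np.zeros(3))
        s = lstm_cell_step(p, LSTMState(np.zeros(3), np.zeros(3)), np.zeros(2))
        assert np.allclose(s.cell, 0.0) and np.allclose(s.hidden, 0.0)

    def test_zero_weights_with_unit_cell_state(self):
        # gates all 0.5: c1 = 0.5 * 1 = 0.5, h1 = 0.5 * tanh(0.5)
        p = LSTMCellParams(np.zeros((9, 5)), np.zeros(9), np.zeros((3, 5)), np.zeros(3))
        s = lstm_cell_step(p, LSTMState(np.ones(3), np.zeros(3)), np.zeros(2))
        assert np.allclose(s.cell, 0.5)
        assert np.allclose(s.hidden, 0.5 * np.tanh(0.5))
        assert s.hidden[0] == pytest.approx(0.23105857863, abs=1e-9)

    def test_ten_steps_match_scalar_oracle(self, rng):
        hsz, d = 5, 3
        p = random_params(rng, hsz, d)
        c = np.zeros(hsz)
        h = np.zeros(hsz)
        co, ho = list(c), list(h)
        for _ in range(10):
            x = rng.normal(size=d)
            s = lstm_cell_step(p, LSTMState(c, h), x)
            c, h = s.cell, s.hidden
            co, ho = scalar_cell_step(p, co, ho, list(x))
            assert np.max(np.abs(c - np.array(co))) < 1e-6
            assert np.max(np.abs(h - np.array(ho))) < 1e-6

    def test_hidden_state_bounded_by_one(self, rng):
        p = random_params(rng, 4, 2)
        s = LSTMState(np.zeros(4), np.zeros(4))
        for _ in range(20):
            s = lstm_cell_step(p, s, rng.normal(scale=3.0, size=2))
            assert np.all(np.abs(s.hidden) <= 1.0)

    def test_shape_mismatch_raises(self, rng):
        p = random_params(rng, 4, 2)
        with pytest.raises(ValueError, match="input size"):
            lstm_cell_step(p, LSTMState(np.zeros(4), np.zeros(4)), np.zeros(7))


def _tiny_model(**kw):
    defaults = dict(lstm_layers=2, lstm_units=6, dense_units=4, dropout=0.0, seed=0)
    defaults.update(kw)
    return ContactModel(ModelConfig(**defaults), input_dim=4)


class TestForward:
    def test_all_zero_weights_give_probability_half(self):
        m = _tiny_model()
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        x = np.random.default_rng(0).normal(size=(1, 1, 4))
        proba = m.predict_proba(x, np.ones((1, 1)))
        assert proba[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        m = _tiny_model()
        proba = m.predict_proba(rng.normal(size=(3, 20, 4)), np.ones((3, 20)))
        assert np.all(proba > 0.0) and np.all(proba < 1.0)

    def test_bidirectional_symmetry_under_time_reversal(self, rng):
        # exchanging the forward/backward cells also swaps the order of their
        # concatenated outputs, so the input blocks of the next layer and of
        # the dense layer must be swapped along with them
        m = _tiny_model()
        swapped = _tiny_model()
        h = m.config.lstm_units

        def rowswap(w):
            return np.concatenate([w[h : 2 * h], w[:h]], axis=0)

        for layer in range(2):
            for k in ("Wx", "Wh", "b"):
                swapped.params[f"l{layer}_fw_{k}"] = m.params[f"l{layer}_bw_{k}"].copy()
                swapped.params[f"l{layer}_bw_{k}"] = m.params[f"l{layer}_fw_{k}"].copy()
        for direction in ("fw", "bw"):
            swapped.params[f"l1_{direction}_Wx"] = rowswap(swapped.params[f"l1_{direction}_Wx"])
        for k in ("dense_b", "out_w", "out_b"):
            swapped.params[k] = m.params[k].copy()
        swapped.params["dense_W"] = rowswap(m.params["dense_W"])
        x = rng.normal(size=(2, 15, 4))
        mask = np.ones((2, 15))
        a = m.predict_proba(x, mask)
        b = swapped.predict_proba(x[:, ::-1], mask)
        assert np.allclose(a, b[:, ::-1], atol=1e-10)

    def test_masked_prefix_probability_is_half(self, rng):
        # padded positions reproduce the 0.5 placeholder output and are never scored
        m = _tiny_model()
        x = rng.normal(size=(2, 20, 4))
        mask = np.ones((2, 20))
        mask[:, :8] = 0
        proba = m.predict_proba(x, mask)
        assert np.allclose(proba[:, :8], 0.5)


class TestMaskingInvariance:
    def test_padding_values_do_not_affect_loss_or_accuracy(self, rng):
        m = _tiny_model()
        x = rng.normal(size=(4, 30, 4))
        y = (rng.random((4, 30)) < 0.5).astype(float)
        mask = np.ones((4, 30))
        mask[:, :10] = 0
        mask[1, 10:13] = 0
        x[mask == 0] = 0
        logits1, _ = m.forward(x, mask)
        xp = x.copy()
        xp[mask == 0] = rng.normal(scale=50.0, size=int((mask == 0).sum() * 4)).reshape(-1, 4)
        logits2, _ = m.forward(xp, mask)
        assert abs(masked_bce(logits1, y, mask) - masked_bce(logits2, y, mask)) < 1e-9
        p1 = 0.5 * (1 + np.tanh(0.5 * logits1))
        p2 = 0.5 * (1 + np.tanh(0.5 * logits2))
        assert abs(masked_accuracy(p1, y, mask) - masked_accuracy(p2, y, mask)) < 1e-9


def _labelled_batch(n_cycles=24, length=60, rate=200.0, seed=0):
    """Separable toy cycles: features switch level inside the contact phase."""
    rng = np.random.default_rng(seed)
    cycles = []
    for i in range(n_cycles):
        fs = rng.integers(10, 20)
        to = rng.integers(35, 50)
        labels = np.zeros(length, dtype=int)
        labels[fs : to + 1] = 1
        feats = rng.normal(scale=0.1, size=(length, 4))
        feats[:, 0] += labels * 2.0 - 1.0
        feats[:, 2] += np.roll(labels, 1) * 1.5
        cycles.append(
            GaitCycle(
                features=FeatureSequence(feats, rate),
                labels=ContactLabelSequence(labels, rate),
                cycle_id=f"t{i}",
                participant_id=f"P{i % 4}",
            )
        )
    return cycles


class TestTraining:
    def test_two_runs_same_seed_give_identical_first_epoch_loss(self):
        cycles = _labelled_batch()
        tb = standardise_and_pad(cycles)
        cfg = dict(lstm_layers=1, lstm_units=6, dense_units=4, dropout=0.3,
                   max_epochs=1, patience=1, seed=7)
        _, h1 = train(ModelConfig(**cfg), tb, tb)
        _, h2 = train(ModelConfig(**cfg), tb, tb)
        assert h1.train_loss[0] == h2.train_loss[0]

    def test_early_stopping_with_flat_validation(self):
        # learning rate 0 freezes the weights, so validation accuracy never
        # improves after epoch 1 and patience 10 stops training at epoch 11
        cycles = _labelled_batch()
        tb = standardise_and_pad(cycles)
        cfg = ModelConfig(lstm_layers=1, lstm_units=4, dense_units=3, dropout=0.0,
                          learning_rate=0.0, max_epochs=100, patience=10, seed=1)
        _, hist = train(cfg, tb, tb)
        assert hist.stopped_early
        assert hist.epochs[-1] == 11
        assert hist.best_epoch == 1

    def test_overfits_separable_cycles_to_perfect_accuracy(self):
        cycles = _labelled_batch(n_cycles=50)
        tb = standardise_and_pad(cycles)
        cfg = ModelConfig(lstm_layers=2, lstm_units=16, dense_units=8, dropout=0.0,
                          max_epochs=100, patience=100, learning_rate=3e-3, seed=2,
                          dtype="float32")
        model, hist = train(cfg, tb, tb)
        assert max(hist.train_accuracy) >= 0.999

    def test_empty_training_set_raises(self):
        cycles = _labelled_batch(n_cycles=4)
        tb = standardise_and_pad(cycles)
        empty = PaddedBatch(
            inputs=np.zeros((0, 200, 4)), targets=np.zeros((0, 200)),
            mask=np.zeros((0, 200)), scaler=tb.scaler, rate=200.0,
        )
        cfg = ModelConfig(lstm_layers=1, lstm_units=4, dense_units=3, seed=0)
        model = ContactModel(cfg)
        with pytest.raises(ValueError, match="empty training set"):
            model.fit(empty, tb)


class TestCrossValidate:
    def test_identical_folds_give_near_zero_accuracy_spread(self):
        cycles = _labelled_batch(n_cycles=12)
        folds = [cycles, list(cycles), list(cycles)]
        cfg = ModelConfig(lstm_layers=1, lstm_units=4, dense_units=3, dropout=0.0,
                          max_epochs=2, patience=2, seed=3, dtype="float32")
        result = cross_validate(cfg, folds)
        assert len(result.fold_accuracies) == 3
        assert np.std(result.fold_accuracies) < 1e-3

    def test_empty_fold_raises(self):
        cycles = _labelled_batch(n_cycles=6)
        cfg = ModelConfig(lstm_layers=1, lstm_units=4, dense_units=3, seed=0)
        with pytest.raises(ValueError, match="fold 1"):
            cross_validate(cfg, [cycles, []])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = ModelConfig(lstm_layers=2, lstm_units=5, dense_units=3, dropout=0.5, seed=4)
        m = ContactModel(cfg, scaler=Scaler(mean=np.arange(4.0), sd=np.ones(4)))
        path = tmp_path / "model.npz"
        m.save(path)
        loaded = ContactModel.load(path)
        x = rng.normal(size=(2, 12, 4))
        mask = np.ones((2, 12))
        assert np.array_equal(m.predict_proba(x, mask), loaded.predict_proba(x, mask))
        assert np.allclose(loaded.scaler.mean, np.arange(4.0))
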