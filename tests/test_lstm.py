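"""Sequence model: recurrence correctness, lock rule, balanced batches, training."""

import math

import numpy as np
import pytest

from fedsepsis import lstm, pipeline, synth
from fedsepsis._rng import child_rng

from conftest import make_grid


def _scalar_sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def _scalar_lstm_step(x, h, c, Wx, Wh, b, eq8_literal=False):
    """Independent scalar-loop recurrence used as the numerical oracle."""
    H = len(h)
    D = len(x)
    z = [0.0] * (4 * H)
    for j in range(4 * H):
        acc = b[j]
        for i in range(D):
            acc += x[i] * Wx[i][j]
        for i in range(H):
            acc += h[i] * Wh[i][j]
        z[j] = acc
    f = [_scalar_sigmoid(z[j]) for j in range(H)]
    gi = [_scalar_sigmoid(z[H + j]) for j in range(H)]
    o = [_scalar_sigmoid(z[2 * H + j]) for j in range(H)]
    cb = [math.tanh(z[3 * H + j]) for j in range(H)]
    c_new = [f[j] * c[j] + gi[j] * cb[j] for j in range(H)]
    gate = f if eq8_literal else o
    h_new = [gate[j] * math.tanh(c_new[j]) for j in range(H)]
    return h_new, c_new


class TestLstmStep:
    def test_all_zero_weights_closed_form(self):
        """sigma(0)=0.5 everywhere, candidate 0, so the state stays at zero."""
        D, H = 3, 2
        h, c = lstm.lstm_step(
            np.ones(D), np.zeros(H), np.zeros(H),
            np.zeros((D, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H),
        )
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    @pytest.mark.parametrize("eq8_literal", [False, True])
    def test_matches_scalar_loop_oracle(self, eq8_literal):
        rng = child_rng(0, "step-oracle")
        for _ in range(10):
            D, H = 3, 3
            x = rng.normal(size=D)
            h0 = rng.normal(size=H)
            c0 = rng.normal(size=H)
            Wx = rng.normal(size=(D, 4 * H))
            Wh = rng.normal(size=(H, 4 * H))
            b = rng.normal(size=4 * H)
            h1, c1 = lstm.lstm_step(x, h0, c0, Wx, Wh, b, eq8_literal=eq8_literal)
            h2, c2 = _scalar_lstm_step(
                x.tolist(), h0.tolist(), c0.tolist(),
                Wx.tolist(), Wh.tolist(), b.tolist(), eq8_literal=eq8_literal,
            )
            np.testing.assert_allclose(h1, h2, atol=1e-10)
            np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_eq8_variant_uses_forget_gate(self):
        rng = child_rng(1, "eq8")
        D, H = 2, 2
        args = (rng.normal(size=D), rng.normal(size=H), rng.normal(size=H),
                rng.normal(size=(D, 4 * H)), rng.normal(size=(H, 4 * H)),
                rng.normal(size=4 * H))
        h_std, c_std = lstm.lstm_step(*args)
        h_lit, c_lit = lstm.lstm_step(*args, eq8_literal=True)
        np.testing.assert_array_equal(c_std, c_lit)  # cell update identical
        assert not np.allclose(h_std, h_lit)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            lstm.lstm_step(
                np.array([np.nan]), np.zeros(1), np.zeros(1),
                np.zeros((1, 4)), np.zeros((1, 4)), np.zeros(4),
            )


def test_window_probabilities_sum_to_one():
    grids = [make_grid(np.random.default_rng(0).normal(size=(6, 3)), label=bool(i % 2))
             for i in range(8)]
    model, _ = lstm.train(grids, lstm.TrainConfig(neurons=4, batch_size=4, seed=0))
    X, _, _ = lstm._pack_batch(grids)
    probs1 = lstm.forward_probabilities(model, X)
    _, _, logits = lstm._forward(model.params, X, model.config)
    total = np.exp(lstm._log_softmax(logits)).sum(axis=-1)
    np.testing.assert_allclose(total, 1.0, atol=1e-8)
    assert np.all((probs1 >= 0) & (probs1 <= 1))


class TestLockRule:
    def test_lock_at_first_crossing(self):
        lock, score = lstm.lock_and_score([0.2, 0.6, 0.9])
        assert lock == 1 and score == 0.6

    def test_no_lock_scores_max(self):
        lock, score = lstm.lock_and_score([0.2, 0.5, 0.4])
        assert lock is None and score == 0.5

    def test_exact_half_is_not_a_lock(self):
        lock, _ = lstm.lock_and_score([0.5, 0.5])
        assert lock is None


class TestBalancedBatches:
    def _pool(self, n=400, prevalence=0.095, seed=0):
        rng = child_rng(seed, "pool")
        return [
            make_grid(np.zeros((3, 1)), label=bool(rng.random() < prevalence),
                      episode_id=f"e{i}")
            for i in range(n)
        ]

    def test_every_batch_exactly_half_positive(self):
        batches = lstm.make_balanced_batches(self._pool(), 100, seed=1)
        for batch in batches:
            assert len(batch) == 100
            assert sum(g.label for g in batch) == 50

    def test_odd_batch_size_rounds_positives_up(self):
        batches = lstm.make_balanced_batches(self._pool(), 9, seed=1)
        for batch in batches:
            assert len(batch) == 9
            assert sum(g.label for g in batch) == 5

    def test_negatives_covered_once(self):
        pool = self._pool(n=103)
        batches = lstm.make_balanced_batches(pool, 10, seed=2)
        seen = [g.episode_id for b in batches for g in b if not g.label]
        n_neg = sum(not g.label for g in pool)
        assert set(seen) == {g.episode_id for g in pool if not g.label}
        assert len(batches) == math.ceil(n_neg / 5)

    def test_deterministic_under_seed(self):
        pool = self._pool()
        a = lstm.make_balanced_batches(pool, 20, seed=3)
        b = lstm.make_balanced_batches(pool, 20, seed=3)
        assert [[g.episode_id for g in batch] for batch in a] == [
            [g.episode_id for g in batch] for batch in b
        ]

    def test_single_class_rejected(self):
        pool = [make_grid(np.zeros((2, 1)), label=False)] * 10
        with pytest.raises(ValueError):
            lstm.make_balanced_batches(pool, 4)


class TestTrain:
    def _separable_grids(self, n=60, seed=0):
        rng = child_rng(seed, "sep")
        grids = []
        for i in range(n):
            label = i % 2 == 0
            shift = 1.5 if label else -1.5
            grids.append(
                make_grid(rng.normal(size=(5, 2)) + shift, label=label,
                          episode_id=f"e{i}")
            )
        return grids

    def test_loss_decreases_on_separable_data(self):
        grids = self._separable_grids()
        _, losses = lstm.train(
            grids, lstm.TrainConfig(neurons=8, batch_size=10, epochs=2, seed=0)
        )
        assert losses[-1] < losses[0]

    def test_training_is_deterministic_without_dropout(self):
        grids = self._separable_grids()
        cfg = lstm.TrainConfig(neurons=4, batch_size=10, dropout=0, seed=5)
        m1, _ = lstm.train(grids, cfg)
        m2, _ = lstm.train(grids, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_single_episode_overfit(self):
        """200 Adam steps drive one episode's loss below 0.05."""
        rng = child_rng(2, "overfit")
        g = make_grid(rng.normal(size=(6, 3)), label=True)
        cfg = lstm.TrainConfig(neurons=8, seed=2)
        X, valid, labels = lstm._pack_batch([g])
        params = lstm.init_params(3, cfg, child_rng(2, "init"))
        keys = sorted(params)
        opt = lstm.Adam([params[k] for k in keys], lr=cfg.learning_rate)
        for _ in range(200):
            loss, grads = lstm._loss_and_grads(params, X, valid, labels, cfg, None)
            opt.step([grads[k] for k in keys])
        assert loss < 0.05

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            lstm.train([], lstm.TrainConfig())

    def test_non_finite_features_rejected(self):
        g = make_grid(np.array([[np.nan], [1.0]]), mask=np.array([[0], [1]]))
        with pytest.raises(ValueError, match="non-finite"):
            lstm._pack_batch([g])


class TestRandomSearch:
    def _data(self):
        rng = child_rng(3, "rs")
        grids = [
            make_grid(rng.normal(size=(4, 2)) + (1.0 if i % 2 else -1.0),
                      label=bool(i % 2), episode_id=f"e{i}")
            for i in range(30)
        ]
        return grids[:20], grids[20:]

    def test_single_draw_returns_that_config(self):
        train_g, tune_g = self._data()
        grid = {"neurons": (4,), "epochs": (1,)}
        best, history = lstm.random_search(
            train_g, tune_g, grid=grid, n_draws=1, seed=0,
            base_config=lstm.TrainConfig(batch_size=10),
        )
        assert len(history) == 1
        assert best.neurons == 4 and best.epochs == 1

    def test_overdrawn_grid_capped_with_warning(self):
        train_g, tune_g = self._data()
        grid = {"neurons": (2, 4), "epochs": (1,)}
        with pytest.warns(UserWarning, match="exceeds grid size"):
            _, history = lstm.random_search(
                train_g, tune_g, grid=grid, n_draws=10, seed=0,
                base_config=lstm.TrainConfig(batch_size=10),
            )
        assert len(history) == 2  # exhaustive

    def test_search_is_deterministic(self):
        train_g, tune_g = self._data()
        grid = {"neurons": (2, 4), "epochs": (1, 2)}
        best1, _ = lstm.random_search(
            train_g, tune_g, grid=grid, n_draws=3, seed=4,
            base_config=lstm.TrainConfig(batch_size=10),
        )
        best2, _ = lstm.random_search(
            train_g, tune_g, grid=grid, n_draws=3, seed=4,
            base_config=lstm.TrainConfig(batch_size=10),
        )
        assert best1 == best2


def test_model_checkpoint_round_trip(tmp_path):
    grids = [make_grid(np.random.default_rng(1).normal(size=(4, 2)), label=bool(i % 2))
             for i in range(6)]
    model, _ = lstm.train(grids, lstm.TrainConfig(neurons=4, batch_size=4, seed=1))
    path = tmp_path / "model.npz"
    lstm.save_model(model, path)
    loaded = lstm.load_model(path)
    assert loaded.config == model.config
    for k in model.params:
        np.testing.assert_array_equal(loaded.params[k], model.params[k])


def test_informative_signal_beats_prevalence_baseline():
    """Tune-split AUPRC clears the prevalence floor by at least 0.2 (3 seeds)."""
    from fedsepsis import metrics

    margins = []
    for seed in (1, 2, 3):
        cfg = synth.SynthConfig(n_patients=2000, seed=seed)
        preset = pipeline.ExperimentPreset(modality="non_text", missingness="cfmean", seed=seed)
        data = pipeline.build_dataset(cfg, preset)
        model, _ = lstm.train(
            data.splits["train"], lstm.TrainConfig(epochs=2, seed=seed)
        )
        tune = data.splits["tune"]
        scores = np.array([lstm.predict_episode(g, model).episode_score for g in tune])
        labels = np.array([g.label for g in tune])
        margins.append(metrics.auprc(scores, labels) - labels.mean())
    assert sum(m >= 0.2 for m in margins) >= 2, margins
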