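"""Network construction, forward pass, schedule arithmetic, training."""

import math

import numpy as np
import pandas as pd
import pytest

from scintiseg.features import FEATURE_COLUMNS
from scintiseg.mfdn import (HIDDEN_WIDTHS, TrainConfig, build_model, forward,
                            load_model, lr_at_epoch, planned_iterations,
                            predict_labelmap, save_model, train)


def naive_forward(model, x):
    """Independent per-sample reimplementation of the layer recursion and
    softmax: explicit loops over nodes, bias node m_0 = 1."""
    acts = {"relu": lambda r: max(0.0, r),
            "sigmoid": lambda r: 1.0 / (1.0 + math.exp(-r)),
            "tanh": math.tanh}
    s = acts[model.activation]
    a = list(map(float, x))
    for k, w in enumerate(model.weights):
        m = [1.0] + a                    # prepend the bias node
        out = []
        for p in range(w.shape[1]):
            r = sum(w[t, p] * m[t] for t in range(w.shape[0]))
            out.append(r)
        if k < len(model.weights) - 1:
            a = [s(r) for r in out]
        else:
            mx = max(out)
            e = [math.exp(r - mx) for r in out]
            z = sum(e)
            a = [v / z for v in e]
    return np.array(a)


def _table(X, y):
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "patch_id", "t")
    df.insert(1, "row", 0)
    df.insert(2, "col", 0)
    df["label"] = y
    return df


class TestBuild:
    def test_parameter_count_closed_form(self):
        model = build_model(6, seed=0)
        widths = [6, *HIDDEN_WIDTHS, 3]
        expected = sum((n_in + 1) * n_out
                       for n_in, n_out in zip(widths[:-1], widths[1:]))
        assert model.n_parameters == expected
        # ten fully connected layers: nine activated hidden layers plus the
        # 3-unit class-score layer feeding softmax
        assert len(model.weights) == 10
        assert model.weights[-1].shape[1] == 3

    def test_shapes_chain(self):
        model = build_model(6, seed=1)
        for w, n_in, n_out in zip(model.weights, model.widths[:-1], model.widths[1:]):
            assert w.shape == (n_in + 1, n_out)

    def test_seeded_init_reproducible(self):
        a = build_model(6, seed=7)
        b = build_model(6, seed=7)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError):
            build_model(6, activation="swish")

    def test_activation_definitions(self):
        from scintiseg.mfdn import _ACTIVATIONS
        relu = _ACTIVATIONS["relu"][0]
        sig = _ACTIVATIONS["sigmoid"][0]
        assert relu(np.array(-1.0)) == 0.0
        assert relu(np.array(2.0)) == 2.0
        assert sig(np.array(0.0)) == 0.5


class TestForward:
    def test_zero_weights_uniform(self):
        model = build_model(6, seed=0)
        for w in model.weights:
            w[...] = 0.0
        probs = forward(model, np.random.default_rng(0).random((4, 6)))
        np.testing.assert_allclose(probs, 1.0 / 3.0)

    def test_rows_sum_to_one(self):
        model = build_model(6, seed=2)
        probs = forward(model, np.random.default_rng(1).random((20, 6)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_softmax_shift_invariance(self):
        model = build_model(6, seed=3)
        X = np.random.default_rng(2).random((5, 6))
        p1 = forward(model, X)
        model.weights[-1][0] += 13.7     # constant added to every output logit
        p2 = forward(model, X)
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    @pytest.mark.parametrize("activation", ["relu", "sigmoid", "tanh"])
    def test_matches_naive_oracle(self, activation):
        model = build_model(6, activation=activation, seed=4)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 6))
        probs = forward(model, X)
        for i in range(5):
            np.testing.assert_allclose(probs[i], naive_forward(model, X[i]),
                                       atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        model = build_model(6, seed=5)
        with pytest.raises(ValueError):
            forward(model, np.zeros((3, 5)))


class TestSchedule:
    def test_lr_values(self):
        cfg = TrainConfig(epochs=20)
        assert lr_at_epoch(cfg, 1) == pytest.approx(1e-3)
        assert lr_at_epoch(cfg, 10) == pytest.approx(1e-3)
        assert lr_at_epoch(cfg, 11) == pytest.approx(1e-4)
        assert lr_at_epoch(cfg, 20) == pytest.approx(1e-4)

    def test_epoch_out_of_range(self):
        cfg = TrainConfig(epochs=20)
        with pytest.raises(ValueError):
            lr_at_epoch(cfg, 0)
        with pytest.raises(ValueError):
            lr_at_epoch(cfg, 21)

    def test_reference_schedule_total(self):
        per_epoch, total = planned_iterations(680_832, 64, 20)
        assert per_epoch == 10_638
        assert total == 212_760

    def test_single_batch(self):
        assert planned_iterations(64, 64, 1) == (1, 1)

    def test_matches_loop_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(1, 5000))
            b = int(rng.integers(1, n + 1))
            e = int(rng.integers(1, 6))
            count = 0
            for _epoch in range(e):
                i = 0
                while i + b <= n:   # full mini-batches only
                    count += 1
                    i += b
            per, total = planned_iterations(n, b, e)
            assert total == count
            assert per * e == count

    def test_batch_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            planned_iterations(10, 64, 1)


class TestTraining:
    def test_initial_balanced_loss_is_ln3(self):
        """Zero output logits on balanced 3-class data give loss ln 3."""
        rng = np.random.default_rng(10)
        X = rng.random((300, 6))
        y = np.repeat([0, 1, 2], 100)
        model = build_model(6, seed=0)
        model.weights[-1][...] = 0.0
        probs = forward(model, X)
        loss = -np.mean(np.log(probs[np.arange(300), y]))
        assert loss == pytest.approx(np.log(3), abs=1e-9)

    def test_separable_toy_problem_learned(self):
        """Two informative features linearly separate three classes; the
        network reaches >=99% training accuracy in 5 epochs.  (Logistic
        regression confirms the construction is separable.)"""
        rng = np.random.default_rng(11)
        n = 3000
        y = rng.integers(0, 3, n)
        centers = np.array([[0.1, 0.1], [0.9, 0.1], [0.5, 0.9]])
        X = np.zeros((n, 6))
        X[:, :2] = centers[y] + rng.normal(0, 0.05, (n, 2))
        X[:, 2:] = rng.random((n, 4))
        from sklearn.linear_model import LogisticRegression
        assert LogisticRegression(max_iter=1000).fit(X[:, :2], y).score(X[:, :2], y) > 0.999
        model = build_model(6, seed=1)
        model, curve = train(model, _table(X, y), None,
                             TrainConfig(epochs=5, seed=2,
                                         validation_frequency=10 ** 9))
        probs = forward(model, X)
        acc = np.mean(probs.argmax(axis=1) == y)
        assert acc >= 0.99
        # loss decreases from start to finish
        assert curve["train_loss"].iloc[-5:].mean() < curve["train_loss"].iloc[:5].mean()

    def test_zero_epochs_noop(self):
        rng = np.random.default_rng(12)
        X, y = rng.random((100, 6)), rng.integers(0, 3, 100)
        model = build_model(6, seed=3)
        before = [w.copy() for w in model.weights]
        model, curve = train(model, _table(X, y), None, TrainConfig(epochs=0, seed=0))
        assert curve.empty
        for w, b in zip(model.weights, before):
            assert np.array_equal(w, b)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(13)
        X = rng.random((100, 6))
        with pytest.raises(ValueError):
            train(build_model(6, seed=0), _table(X, np.zeros(100, dtype=int)),
                  None, TrainConfig(epochs=1, seed=0))

    def test_training_bit_reproducible(self):
        rng = np.random.default_rng(14)
        X, y = rng.random((640, 6)), rng.integers(0, 3, 640)
        tbl = _table(X, y)
        cfg = TrainConfig(epochs=2, seed=5, validation_frequency=3)
        m1, c1 = train(build_model(6, seed=6), tbl, tbl.iloc[:100], cfg)
        m2, c2 = train(build_model(6, seed=6), tbl, tbl.iloc[:100], cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)
        assert c1.equals(c2)

    def test_validation_recorded_at_frequency(self):
        rng = np.random.default_rng(15)
        X, y = rng.random((640, 6)), rng.integers(0, 3, 640)
        tbl = _table(X, y)
        _, curve = train(build_model(6, seed=7), tbl, tbl.iloc[:64],
                         TrainConfig(epochs=1, seed=8, validation_frequency=4))
        val_iters = curve.loc[curve["val_loss"].notna(), "iteration"]
        assert (val_iters[val_iters < curve["iteration"].max()] % 4 == 0).all()


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        model = build_model(6, seed=20)
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert back.widths == model.widths
        assert back.activation == model.activation
        for w1, w2 in zip(back.weights, model.weights):
            assert np.array_equal(w1, w2)


class TestPredictLabelmap:
    def test_subthreshold_scan_is_all_background(self):
        from scintiseg.priors import estimate_priors
        scan = np.full((32, 32), 100, dtype=np.uint8)
        priors = estimate_priors([np.zeros((32, 32), dtype=np.uint8)])
        model = build_model(6, seed=21)
        res = predict_labelmap(model, scan, priors)
        assert not res.labels.any()
        np.testing.assert_allclose(res.probabilities[0], 1.0)

    def test_probabilities_sum_to_one_everywhere(self, phantom_pair):
        from scintiseg.priors import estimate_priors
        scan, labels = phantom_pair
        priors = estimate_priors([labels])
        model = build_model(6, seed=22)
        res = predict_labelmap(model, scan, priors)
        np.testing.assert_allclose(res.probabilities.sum(axis=0), 1.0, atol=1e-9)
        # argmax consistency on the foreground
        from scintiseg.preprocess import threshold_mask
        mask = threshold_mask(scan)
        np.testing.assert_array_equal(res.labels[mask],
                                      res.probabilities[:, mask].argmax(axis=0))

    def test_prior_shape_mismatch_rejected(self, phantom_pair):
        from scintiseg.priors import estimate_priors
        scan, _ = phantom_pair
        priors = estimate_priors([np.zeros((10, 10), dtype=np.uint8)])
        model = build_model(6, seed=23)
        with pytest.raises(ValueError):
            predict_labelmap(model, scan, priors)
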