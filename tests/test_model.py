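import numpy as np
import pandas as pd
import pytest

from circlearn import _nn
from circlearn.model import (CnnBlstmNet, EvalReport, ModelConfig,
                             TrainedModel, block_structure, build_model,
                             crossvalidate, metrics, train)


def toy_matrix(rng, n=60, sep=4.0):
    """Linearly separable two-block toy problem."""
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 10))
    X[:, 0] += sep * y
    X[:, 7] -= sep * y
    cols = [f"rcm{i+1}" for i in range(6)] + [f"seq{i+1}" for i in range(4)]
    return pd.DataFrame(X, columns=cols), y


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            ModelConfig(conv_filters=0)

    def test_block_structure_grouping(self):
        cols = ["rcm1", "rcm_total", "con1", "graph2", "seq1", "seq2"]
        blocks = block_structure(cols)
        assert list(blocks) == ["rcm", "con", "graph", "seq"]
        assert blocks["rcm"] == ["rcm1", "rcm_total"]


class TestNetwork:
    def test_four_parallel_branches_and_output_width(self):
        net = build_model(ModelConfig.small(), {"rcm": 10, "con": 8,
                                                "graph": 12, "seq": 9})
        conv_params = [k for k in net.params if k.startswith("conv_")
                       and k.endswith("_W")]
        assert len(conv_params) == 4
        assert net.params["dense2_W"].shape[1] == 2

    def test_forward_on_zeros_gives_valid_probabilities(self):
        net = build_model(ModelConfig.small(), {"rcm": 6, "seq": 5})
        probs = net.predict_proba_blocks({"rcm": np.zeros((3, 6)),
                                          "seq": np.zeros((3, 5))})
        assert np.all(np.isfinite(probs))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_narrow_block_rejected_with_padding_hint(self):
        with pytest.raises(ValueError, match="pad"):
            build_model(ModelConfig.small(), {"rcm": 2})

    def test_gradients_match_numerical(self, rng):
        """Backprop through conv/BN/pool/BiLSTM/dense agrees with central
        finite differences."""
        cfg = ModelConfig(conv_filters=3, conv_kernel=3, lstm_units=4,
                          dense_sizes=(5, 4), dropout=0.0, seed=1)
        net = CnnBlstmNet(cfg, {"rcm": 7, "seq": 6})
        X = {"rcm": rng.normal(size=(5, 7)), "seq": rng.normal(size=(5, 6))}
        y = np.array([0, 1, 0, 1, 1])

        def loss_fn():
            logits, caches = net._forward(X, train=True)
            loss, dl, _ = _nn.softmax_xent_loss_grad(logits, y)
            return loss, dl, caches

        _, dl, caches = loss_fn()
        grads = net._backward(dl, caches)
        eps = 1e-6
        for name, p in net.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _, _ = loss_fn()
            p[idx] = orig - eps
            lm, _, _ = loss_fn()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name][idx]
            assert ana == pytest.approx(num, abs=1e-5, rel=1e-4), name


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self, rng):
        X, y = toy_matrix(rng)
        cfg = ModelConfig(conv_filters=4, lstm_units=4, dense_sizes=(16, 8),
                          dropout=0.0, learning_rate=5e-3, batch_size=16,
                          max_epochs=120, patience=120, seed=0)
        fitted = train(X, y, config=cfg)
        assert fitted.history["train_acc"].max() == 1.0
        assert (fitted.predict(X) == y).mean() >= 0.9

    def test_fixed_seed_reproduces_history(self, rng):
        X, y = toy_matrix(rng)
        cfg = ModelConfig.small(seed=3)
        cfg.max_epochs = 8
        cfg.min_epochs = 0
        h1 = train(X, y, config=cfg).history
        h2 = train(X, y, config=cfg).history
        pd.testing.assert_frame_equal(h1, h2)
        assert len(h1) >= 1

    def test_predict_proba_rows_sum_to_one(self, rng):
        X, y = toy_matrix(rng)
        cfg = ModelConfig.small(seed=0)
        cfg.max_epochs, cfg.min_epochs = 5, 0
        fitted = train(X, y, config=cfg)
        probs = fitted.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # deterministic inference
        assert np.array_equal(probs, fitted.predict_proba(X))

    def test_single_class_rejected(self, rng):
        X, _ = toy_matrix(rng)
        with pytest.raises(ValueError):
            train(X, np.zeros(len(X)), config=ModelConfig.small())

    def test_save_load_roundtrip(self, rng, tmp_path):
        X, y = toy_matrix(rng)
        cfg = ModelConfig.small(seed=0)
        cfg.max_epochs, cfg.min_epochs = 5, 0
        fitted = train(X, y, config=cfg)
        fitted.save(tmp_path / "model")
        loaded = TrainedModel.load(tmp_path / "model")
        assert np.allclose(fitted.predict_proba(X), loaded.predict_proba(X))


def confusion_oracle(y_true, y_pred):
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 1 and p == 0:
            fn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            tn += 1
    n = len(y_true)
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom ** 0.5
    return se, sp, acc, mcc


class TestMetrics:
    def test_perfect_prediction(self):
        rep = metrics([1, 0, 1, 0], [1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert (rep.se, rep.sp, rep.acc, rep.mcc, rep.auc) == (1, 1, 1, 1, 1)

    def test_hand_worked_confusion(self):
        y_true = [1] * 50 + [0] * 50
        y_pred = [1] * 50 + [1] * 10 + [0] * 40
        rep = metrics(y_true, y_pred)
        assert rep.se == 1.0 and rep.sp == pytest.approx(0.8)
        assert rep.acc == pytest.approx(0.9)
        assert rep.mcc == pytest.approx(0.8165, abs=1e-4)

    def test_degenerate_marginals_give_zero_mcc(self):
        rep = metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert rep.mcc == 0.0

    def test_matches_oracle_on_1000_random_cases(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 22))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            rep = metrics(y_true, y_pred)
            se, sp, acc, mcc = confusion_oracle(y_true, y_pred)
            assert (rep.se, rep.sp, rep.acc) == (se, sp, acc)
            assert rep.mcc == pytest.approx(mcc, abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        s = rng.random(100)
        assert metrics(y, (s > .5).astype(int), s).auc == pytest.approx(
            roc_auc_score(y, s))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1, 0], [1])


class TestCrossvalidate:
    def test_fold_partitioning_and_determinism(self, rng):
        X, y = toy_matrix(rng, n=100)
        cfg = ModelConfig.small(seed=0)
        cfg.max_epochs, cfg.min_epochs, cfg.patience = 4, 0, 2
        r1 = crossvalidate(X, y, folds=5, seed=0, config=cfg, select_d=6)
        r2 = crossvalidate(X, y, folds=5, seed=0, config=cfg, select_d=6)
        assert len(r1.per_fold) == 5
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)

    def test_too_many_folds_rejected(self, rng):
        X, y = toy_matrix(rng, n=10)
        with pytest.raises(ValueError):
            crossvalidate(X, y, folds=6, seed=0)

    def test_selection_is_fold_local(self, rng, monkeypatch):
        """select_features must only ever see training-fold rows."""
        X, y = toy_matrix(rng, n=40)
        seen_sizes = []
        import circlearn.model as model_mod
        real = model_mod.select_features

        def spy(matrix, labels, **kw):
            seen_sizes.append(matrix.shape[0])
            return real(matrix, labels, **kw)

        monkeypatch.setattr(model_mod, "select_features", spy)
        cfg = ModelConfig.small(seed=0)
        cfg.max_epochs, cfg.min_epochs, cfg.patience = 2, 0, 1
        crossvalidate(X, y, folds=4, seed=0, config=cfg, select_d=5)
        assert seen_sizes == [30, 30, 30, 30]  # never the full 40
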