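"""CNN-BiLSTM classifier, training loop, cross-validation and metrics.

Each feature block (rcm / con / graph / seq) enters its own convolutional
branch — the block is treated as a 1-D sequence of feature positions —
consisting of a valid convolution, batch normalization, ReLU and
max-pooling.  Branch outputs are concatenated along the position axis and
read by a bidirectional LSTM; the final forward and backward hidden states
feed two ReLU dense layers with dropout and a 2-way softmax.  Training
uses Adam with early stopping on validation accuracy (best weights
restored).  Everything is seeded and single-threaded, so runs are
bit-reproducible.
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _nn
from .selection import select_features

BLOCK_ORDER = ("rcm", "con", "graph", "seq")


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults follow the reference architecture: 64 conv filters of kernel
    3 with batch norm and pool 2 per block, a 64-unit-per-direction BiLSTM,
    dense 128 -> 64 with ReLU and dropout 0.5, softmax output, Adam at
    learning rate 0.001, batch size 64, up to 200 epochs with early
    stopping (patience 10 on validation accuracy).
    """

    conv_filters: int = 64
    conv_kernel: int = 3
    pool_size: int = 2
    lstm_units: int = 64
    dense_sizes: tuple[int, int] = (128, 64)
    dropout: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    min_epochs: int = 0
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("conv_filters", "conv_kernel", "pool_size", "lstm_units",
                     "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def small(cls, seed: int = 0) -> "ModelConfig":
        """A compact preset for desk-scale experiments and tests."""
        return cls(conv_filters=8, lstm_units=8, dense_sizes=(32, 16),
                   dropout=0.3, learning_rate=3e-3, batch_size=32,
                   max_epochs=100, patience=15, min_epochs=40, seed=seed)


class CnnBlstmNet:
    """The network itself: parameters, forward pass and backpropagation."""

    def __init__(self, config: ModelConfig, block_dims: Mapping[str, int]):
        if not 1 <= len(block_dims) <= 4:
            raise ValueError("expected between 1 and 4 feature blocks")
        k = config.conv_kernel
        for name, dim in block_dims.items():
            if dim < k:
                raise ValueError(
                    f"block {name!r} has dimension {dim} < kernel {k}; "
                    "pad the block with zero columns or reduce the kernel")
        self.config = config
        self.block_dims = dict(block_dims)
        rng = np.random.default_rng(config.seed)
        F, U = config.conv_filters, config.lstm_units
        p: dict[str, np.ndarray] = {}
        for name in self.block_dims:
            p[f"conv_{name}_W"] = rng.normal(0, np.sqrt(2.0 / k), (k, F))
            p[f"conv_{name}_b"] = np.zeros(F)
            p[f"bn_{name}_gamma"] = np.ones(F)
            p[f"bn_{name}_beta"] = np.zeros(F)
        for d in ("f", "b"):
            p[f"lstm_{d}_Wx"] = rng.normal(0, np.sqrt(1.0 / F), (F, 4 * U))
            p[f"lstm_{d}_Wh"] = rng.normal(0, np.sqrt(1.0 / U), (U, 4 * U))
            p[f"lstm_{d}_b"] = np.zeros(4 * U)
        widths = (2 * U,) + tuple(config.dense_sizes) + (2,)
        for i, (din, dout) in enumerate(zip(widths, widths[1:])):
            p[f"dense{i}_W"] = rng.normal(0, np.sqrt(2.0 / din), (din, dout))
            p[f"dense{i}_b"] = np.zeros(dout)
        self.params = p
        self.bn_running = {name: {"mean": np.zeros(F), "var": np.ones(F)}
                           for name in self.block_dims}
        self.history: pd.DataFrame | None = None

    # ------------------------------------------------------------- forward

    def _forward(self, blocks: Mapping[str, np.ndarray], train: bool,
                 rng: np.random.Generator | None = None):
        cfg, p = self.config, self.params
        caches: dict = {"blocks": {}}
        branch_outs = []
        for name in self.block_dims:
            x = blocks[name]
            z, c_conv = _nn.conv1d_forward(x, p[f"conv_{name}_W"],
                                           p[f"conv_{name}_b"])
            z, c_bn = _nn.bn_forward(z, p[f"bn_{name}_gamma"],
                                     p[f"bn_{name}_beta"],
                                     self.bn_running[name], train)
            z, c_relu = _nn.relu_forward(z)
            z, c_pool = _nn.maxpool_forward(z, cfg.pool_size)
            caches["blocks"][name] = (c_conv, c_bn, c_relu, c_pool, z.shape[1])
            branch_outs.append(z)
        seq = np.concatenate(branch_outs, axis=1)  # (B, T, F)
        h_f, c_lf = _nn.lstm_forward(seq, p["lstm_f_Wx"], p["lstm_f_Wh"],
                                     p["lstm_f_b"])
        h_b, c_lb = _nn.lstm_forward(seq[:, ::-1], p["lstm_b_Wx"],
                                     p["lstm_b_Wh"], p["lstm_b_b"])
        feat = np.concatenate([h_f[:, -1], h_b[:, -1]], axis=1)
        caches["lstm"] = (c_lf, c_lb, seq.shape)
        acts = feat
        dense_caches = []
        n_dense = len(cfg.dense_sizes)
        for i in range(n_dense + 1):
            acts, c_d = _nn.dense_forward(acts, p[f"dense{i}_W"],
                                          p[f"dense{i}_b"])
            if i < n_dense:
                acts, c_r = _nn.relu_forward(acts)
                acts, c_do = _nn.dropout_forward(acts, cfg.dropout, train, rng)
                dense_caches.append((c_d, c_r, c_do))
            else:
                dense_caches.append((c_d, None, None))
        caches["dense"] = dense_caches
        return acts, caches

    def _backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        d = dlogits
        n_dense = len(cfg.dense_sizes)
        for i in range(n_dense, -1, -1):
            c_d, c_r, c_do = caches["dense"][i]
            if i < n_dense:
                d = _nn.dropout_backward(d, c_do)
                d = _nn.relu_backward(d, c_r)
            d, grads[f"dense{i}_W"], grads[f"dense{i}_b"] = \
                _nn.dense_backward(d, c_d)
        U = cfg.lstm_units
        c_lf, c_lb, seq_shape = caches["lstm"]
        B, T, F = seq_shape
        dh_f = np.zeros((B, T, U))
        dh_f[:, -1] = d[:, :U]
        dh_b = np.zeros((B, T, U))
        dh_b[:, -1] = d[:, U:]
        dseq_f, gWx, gWh, gb = _nn.lstm_backward(dh_f, c_lf)
        grads["lstm_f_Wx"], grads["lstm_f_Wh"], grads["lstm_f_b"] = gWx, gWh, gb
        dseq_b, gWx, gWh, gb = _nn.lstm_backward(dh_b, c_lb)
        grads["lstm_b_Wx"], grads["lstm_b_Wh"], grads["lstm_b_b"] = gWx, gWh, gb
        dseq = dseq_f + dseq_b[:, ::-1]
        offset = 0
        for name in self.block_dims:
            c_conv, c_bn, c_relu, c_pool, t_len = caches["blocks"][name]
            dz = dseq[:, offset:offset + t_len]
            offset += t_len
            dz = _nn.maxpool_backward(dz, c_pool)
            dz = _nn.relu_backward(dz, c_relu)
            dz, dgamma, dbeta = _nn.bn_backward(dz, c_bn)
            grads[f"bn_{name}_gamma"] = dgamma
            grads[f"bn_{name}_beta"] = dbeta
            _, dW, db = _nn.conv1d_backward(dz, c_conv)
            grads[f"conv_{name}_W"] = dW
            grads[f"conv_{name}_b"] = db
        return grads

    def predict_proba_blocks(self, blocks: Mapping[str, np.ndarray]
                             ) -> np.ndarray:
        logits, _ = self._forward(blocks, train=False)
        return _nn.softmax(logits)


@dataclass
class TrainedModel:
    """A fitted network plus its feature manifest and training history."""

    net: CnnBlstmNet
    feature_blocks: dict[str, list[str]]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    history: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return [f for cols in self.feature_blocks.values() for f in cols]

    def _blocks_from_matrix(self, X: pd.DataFrame | np.ndarray
                            ) -> dict[str, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_std
        blocks, start = {}, 0
        for name, cols in self.feature_blocks.items():
            dim = len(cols)
            raw = X[:, start:start + dim]
            k = self.net.config.conv_kernel
            if dim < k:  # zero-pad narrow blocks up to the kernel width
                raw = np.pad(raw, ((0, 0), (0, k - dim)))
            blocks[name] = raw
            start += dim
        return blocks

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.net.predict_proba_blocks(self._blocks_from_matrix(X))

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1].round().astype(int)

    def save(self, path: str | Path) -> None:
        """Write parameters (.npz) and a JSON sidecar with the config."""
        path = Path(path)
        arrays = dict(self.net.params)
        for name, stats in self.net.bn_running.items():
            arrays[f"run_{name}_mean"] = stats["mean"]
            arrays[f"run_{name}_var"] = stats["var"]
        arrays["scaler_mean"] = self.scaler_mean
        arrays["scaler_std"] = self.scaler_std
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": asdict(self.net.config),
            "block_dims": self.net.block_dims,
            "feature_blocks": self.feature_blocks,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_d = sidecar["config"]
        cfg_d["dense_sizes"] = tuple(cfg_d["dense_sizes"])
        config = ModelConfig(**cfg_d)
        net = CnnBlstmNet(config, sidecar["block_dims"])
        data = np.load(path.with_suffix(".npz"))
        for key in net.params:
            net.params[key] = data[key]
        for name in net.block_dims:
            net.bn_running[name] = {"mean": data[f"run_{name}_mean"],
                                    "var": data[f"run_{name}_var"]}
        history = pd.DataFrame()
        return cls(net=net, feature_blocks=sidecar["feature_blocks"],
                   scaler_mean=data["scaler_mean"],
                   scaler_std=data["scaler_std"], history=history)


def block_structure(columns: Sequence[str]) -> dict[str, list[str]]:
    """Group feature names into blocks by alphabetic prefix (rcm/con/graph/seq)."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        prefix = "".join(ch for ch in col if ch.isalpha()).replace("_total", "")
        prefix = {"rcmtotal": "rcm"}.get(prefix, prefix)
        groups.setdefault(prefix, []).append(col)
    ordered = {b: groups[b] for b in BLOCK_ORDER if b in groups}
    for b in groups:  # unknown prefixes keep their own block, after the four
        if b not in ordered:
            ordered[b] = groups[b]
    return ordered


def build_model(config: ModelConfig,
                block_dims: Mapping[str, int]) -> CnnBlstmNet:
    """Instantiate an untrained network over the given feature blocks."""
    return CnnBlstmNet(config, block_dims)


def train(matrix: pd.DataFrame, labels, config: ModelConfig | None = None,
          validation_fraction: float | None = None,
          seed: int | None = None) -> TrainedModel:
    """Fit the CNN-BiLSTM on a feature matrix with named columns.

    Features are standardized (train statistics), grouped into blocks by
    name prefix, and fed to the network.  Early stopping monitors
    validation accuracy; the best weights are restored.
    """
    config = config or ModelConfig()
    if seed is not None:
        config = ModelConfig(**{**asdict(config), "seed": seed})
    if validation_fraction is None:
        validation_fraction = config.validation_fraction
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    feature_blocks = block_structure(list(matrix.columns))
    ordered_cols = [c for cols in feature_blocks.values() for c in cols]
    X = matrix[ordered_cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0

    k = config.conv_kernel
    block_dims = {b: max(len(cols), k) for b, cols in feature_blocks.items()}
    net = CnnBlstmNet(config, block_dims)
    model = TrainedModel(net=net, feature_blocks=feature_blocks,
                         scaler_mean=mean, scaler_std=std,
                         history=pd.DataFrame())

    idx = np.arange(len(y))
    tr_idx, va_idx = train_test_split(idx, test_size=validation_fraction,
                                      random_state=config.seed, stratify=y)
    blocks_all = model._blocks_from_matrix(matrix)
    tr_blocks = {b: v[tr_idx] for b, v in blocks_all.items()}
    va_blocks = {b: v[va_idx] for b, v in blocks_all.items()}
    y_tr, y_va = y[tr_idx], y[va_idx]

    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.Adam(net.params, lr=config.learning_rate)
    best_acc, best_loss, best_params, best_running = -1.0, np.inf, None, None
    since_best = 0
    hist_rows = []
    n = len(y_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            bidx = order[start:start + config.batch_size]
            xb = {b: v[bidx] for b, v in tr_blocks.items()}
            yb = y_tr[bidx]
            logits, caches = net._forward(xb, train=True, rng=rng)
            loss, dlogits, probs = _nn.softmax_xent_loss_grad(logits, yb)
            grads = net._backward(dlogits, caches)
            opt.step(net.params, grads)
            epoch_loss += loss * len(bidx)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
        va_probs = net.predict_proba_blocks(va_blocks)
        va_pred = va_probs.argmax(axis=1)
        va_acc = float((va_pred == y_va).mean())
        va_loss = float(-np.log(np.clip(
            va_probs[np.arange(len(y_va)), y_va], 1e-12, None)).mean())
        hist_rows.append({"epoch": epoch, "train_loss": epoch_loss / n,
                          "train_acc": epoch_correct / n,
                          "val_loss": va_loss, "val_acc": va_acc})
        improved = va_acc > best_acc + 1e-12 or (
            va_acc >= best_acc - 1e-12 and va_loss < best_loss - 1e-12)
        if improved:
            best_acc, best_loss = max(best_acc, va_acc), va_loss
            best_params = deepcopy(net.params)
            best_running = deepcopy(net.bn_running)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience and epoch + 1 >= config.min_epochs:
                break
    if best_params is not None:
        net.params = best_params
        net.bn_running = best_running
    model.history = pd.DataFrame(hist_rows)
    net.history = model.history
    return model


# ------------------------------------------------------------------- metrics

@dataclass
class EvalReport:
    """Sensitivity, specificity, accuracy, Matthews correlation and AUC."""

    se: float
    sp: float
    acc: float
    mcc: float
    auc: float
    roc_points: pd.DataFrame | None = None
    per_fold: pd.DataFrame | None = None

    def summary(self) -> pd.Series:
        return pd.Series({"SE": self.se, "SP": self.sp, "ACC": self.acc,
                          "MCC": self.mcc, "AUC": self.auc})


def _rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties handled by mid-ranks)."""
    pos = y_true == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(y_score)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def metrics(y_true, y_pred, y_score=None) -> EvalReport:
    """SE, SP, ACC, MCC (0 on degenerate marginals) and rank-based AUC."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y_true) if len(y_true) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    auc, roc_points = float("nan"), None
    if y_score is not None:
        y_score = np.asarray(y_score, dtype=float)
        auc = _rank_auc(y_true, y_score)
        fpr, tpr, thr = roc_curve(y_true, y_score)
        roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return EvalReport(se=se, sp=sp, acc=acc, mcc=float(mcc), auc=auc,
                      roc_points=roc_points)


def crossvalidate(matrix: pd.DataFrame, labels, folds: int = 10,
                  seed: int = 0, config: ModelConfig | None = None,
                  select_d: int | str | None = 64,
                  ) -> EvalReport:
    """Stratified k-fold evaluation with fold-local feature selection.

    Feature selection (the seven-ranker PageRank ensemble) is fitted on
    each training fold only, so no test information leaks into the chosen
    feature set.  Pass select_d=None to skip selection.
    """
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds the smaller class count "
                         f"({counts.min()})")
    config = config or ModelConfig.small(seed=seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_rows = []
    all_scores = np.zeros(len(y))
    for fold_id, (tr, te) in enumerate(skf.split(matrix, y)):
        X_tr, X_te = matrix.iloc[tr], matrix.iloc[te]
        if select_d is not None:
            d = min(select_d, matrix.shape[1]) if isinstance(select_d, int) \
                else select_d
            ranked, X_tr = select_features(X_tr, y[tr], d=d, seed=seed)
            X_te = X_te[list(ranked.selected)]
        fold_cfg = ModelConfig(**{**asdict(config), "seed": seed + fold_id})
        fitted = train(X_tr, y[tr], config=fold_cfg)
        scores = fitted.predict_proba(X_te)[:, 1]
        all_scores[te] = scores
        rep = metrics(y[te], (scores >= 0.5).astype(int), scores)
        fold_rows.append({"fold": fold_id, "SE": rep.se, "SP": rep.sp,
                          "ACC": rep.acc, "MCC": rep.mcc, "AUC": rep.auc})
    per_fold = pd.DataFrame(fold_rows)
    pooled = metrics(y, (all_scores >= 0.5).astype(int), all_scores)
    return EvalReport(se=float(per_fold["SE"].mean()),
                      sp=float(per_fold["SP"].mean()),
                      acc=float(per_fold["ACC"].mean()),
                      mcc=float(per_fold["MCC"].mean()),
                      auc=float(per_fold["AUC"].mean()),
                      roc_points=pooled.roc_points, per_fold=per_fold)
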