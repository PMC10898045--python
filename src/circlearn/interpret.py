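"""Shapley-value interpretation of the classifier.

Attributions are estimated with the kernel-weighted coalition-regression
formulation of Shapley values (Kernel SHAP): the model is evaluated on
hybrids of the explained sample and background rows, and a weighted least
squares fit under the additivity constraint recovers per-feature
contributions to the positive-class probability.  When the coalition
space is small enough it is enumerated exhaustively, making the estimate
exact; otherwise coalitions are drawn with the Shapley kernel weights,
deterministically for a given seed.

Downstream helpers produce the summary ranking (mean |SHAP| per feature,
with block composition tallies), dependence-pair data (the feature whose
value best explains the residual spread of a target feature's
attributions is chosen for coloring), and long-format violin-plot data.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature Shapley values with a base value.

    base_value is the expected model output over the background set; for
    each row, base_value + sum(values) equals the model output on that
    sample (within estimator tolerance).
    """

    values: np.ndarray
    base_value: float
    feature_names: list[str]
    feature_values: np.ndarray
    model_output: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def _as_function(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model):
        return model
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X))[:, 1]
    raise TypeError("model must be callable or expose predict_proba")


def _kernel_weight(M: int, s: int) -> float:
    M, s = int(M), int(s)
    return (M - 1) / (comb(M, s) * s * (M - s))


def _coalitions(M: int, n_samples: int, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Coalition indicator matrix (excluding empty/full) and kernel weights."""
    if 2 ** M - 2 <= n_samples:
        Z = np.array([[(i >> j) & 1 for j in range(M)]
                      for i in range(1, 2 ** M - 1)], dtype=float)
        w = np.array([_kernel_weight(M, int(z.sum())) for z in Z])
        return Z, w
    sizes = np.arange(1, M)
    # kernel weight x number of coalitions of that size = (M-1)/(s(M-s))
    size_w = np.array([(M - 1) / (int(s) * (M - int(s))) for s in sizes])
    size_p = size_w / size_w.sum()
    rows, weights = [], []
    for _ in range(n_samples // 2):
        s = int(rng.choice(sizes, p=size_p))
        z = np.zeros(M)
        z[rng.choice(M, size=s, replace=False)] = 1.0
        rows.append(z)
        rows.append(1.0 - z)  # paired (antithetic) coalition
        weights.extend([1.0, 1.0])  # sampling already follows the kernel
    return np.asarray(rows), np.asarray(weights)


def shap_values(model, X, background, n_samples: int = 2048,
                seed: int = 0) -> AttributionMatrix:
    """Kernel SHAP attributions of the positive-class output for each row of X.

    model may be a TrainedModel (its positive-class probability is
    explained) or any callable mapping a (n, M) array to n outputs.
    """
    f = _as_function(model)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = background[None, :]
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if background.shape[1] != X.shape[1]:
        raise ValueError(
            f"background has {background.shape[1]} features, X has "
            f"{X.shape[1]}")
    n, M = X.shape
    rng = np.random.default_rng(seed)
    base = float(np.mean(f(background)))
    fx = np.asarray(f(X), dtype=float)
    if M == 1:  # the single feature carries the whole deviation
        phis = (fx - base)[:, None]
        return AttributionMatrix(values=phis, base_value=base,
                                 feature_names=["f0"], feature_values=X,
                                 model_output=fx)
    Z, w = _coalitions(M, n_samples, rng)
    phis = np.zeros((n, M))
    B = background.shape[0]
    for i in range(n):
        # evaluate v(z): background rows with coalition features from x_i
        hybrids = np.repeat(background[None, :, :], len(Z), axis=0)
        mask = Z[:, None, :].astype(bool)
        hybrids = np.where(mask, X[i][None, None, :], hybrids)
        v = f(hybrids.reshape(-1, M)).reshape(len(Z), B).mean(axis=1)
        # constrained WLS: phi_0 = base, sum phi = fx - base
        y = v - base - Z[:, -1] * (fx[i] - base)
        A = Z[:, :-1] - Z[:, -1:]
        lhs = A.T @ (A * w[:, None])
        rhs = A.T @ (w * y)
        phi_rest = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        phis[i, :-1] = phi_rest
        phis[i, -1] = (fx[i] - base) - phi_rest.sum()
    names = list(X.dtype.names) if X.dtype.names else \
        [f"f{j}" for j in range(M)]
    return AttributionMatrix(values=phis, base_value=base,
                             feature_names=names, feature_values=X,
                             model_output=fx)


def shap_for_matrix(model, matrix: pd.DataFrame, background: pd.DataFrame,
                    n_samples: int = 2048, seed: int = 0) -> AttributionMatrix:
    """shap_values over DataFrames, keeping feature names."""
    attr = shap_values(model, matrix.to_numpy(dtype=float),
                       background.to_numpy(dtype=float),
                       n_samples=n_samples, seed=seed)
    attr.feature_names = list(matrix.columns)
    return attr


def _block_of(feature: str) -> str:
    return "".join(ch for ch in feature if ch.isalpha()).replace("total", "")


def summary_rank(attr: AttributionMatrix, top_n: int = 20) -> pd.DataFrame:
    """Features ranked by mean |SHAP|, with their block prefix.

    The block column supports the composition tally of the top-N set
    (how many rcm/con/graph/seq features it contains).
    """
    mean_abs = np.abs(attr.values).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")[:top_n]
    return pd.DataFrame({
        "feature": [attr.feature_names[i] for i in order],
        "block": [_block_of(attr.feature_names[i]) for i in order],
        "mean_abs_shap": mean_abs[order],
    })


def block_tally(summary: pd.DataFrame) -> pd.Series:
    """Count of top-ranked features per block prefix."""
    return summary["block"].value_counts()


def dependence_pair(attr: AttributionMatrix, feature: str,
                    n_bins: int = 10) -> pd.DataFrame:
    """Dependence-plot data for one feature, with an auto-chosen color feature.

    The color feature is the candidate whose values correlate most (in
    absolute value, averaged over value bins of the target feature) with
    the target's attributions — i.e. the feature that best explains the
    vertical spread of the dependence plot.  With a single feature the
    color feature degenerates to the feature itself.
    """
    names = attr.feature_names
    if feature not in names:
        raise KeyError(f"unknown feature {feature!r}")
    j = names.index(feature)
    x = attr.feature_values[:, j]
    y = attr.values[:, j]
    if len(names) == 1:
        color = feature
    else:
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        bins = np.clip(np.searchsorted(edges[1:-1], x), 0, n_bins - 1)
        best_score, color = -1.0, names[0 if j != 0 else 1]
        for cand_j, cand in enumerate(names):
            if cand_j == j:
                continue
            scores, weights = [], []
            for b in np.unique(bins):
                sel = bins == b
                if sel.sum() < 3:
                    continue
                cv, yv = attr.feature_values[sel, cand_j], y[sel]
                if cv.std() == 0 or yv.std() == 0:
                    continue
                scores.append(abs(np.corrcoef(cv, yv)[0, 1]))
                weights.append(sel.sum())
            score = float(np.average(scores, weights=weights)) if scores else 0.0
            if score > best_score + 1e-12:
                best_score, color = score, cand
    cj = names.index(color)
    return pd.DataFrame({
        "feature_value": x,
        "shap_value": y,
        "color_feature": color,
        "color_value": attr.feature_values[:, cj],
    })


def violin_data(matrix: pd.DataFrame, labels,
                features: Sequence[str]) -> pd.DataFrame:
    """Long-format (feature, class, value) table for violin plots.

    Class coding follows the figure convention: "0" is the positive class,
    "1" the negative class.
    """
    y = np.asarray(labels, dtype=int)
    rows = []
    for feat in features:
        if feat not in matrix.columns:
            raise KeyError(f"unknown feature {feat!r}")
        for value, lab in zip(matrix[feat].to_numpy(dtype=float), y):
            rows.append({"feature": feat, "class": 0 if lab == 1 else 1,
                         "value": value})
    return pd.DataFrame(rows)


def top_features_per_block(ranking: pd.DataFrame, per_block: int = 2
                           ) -> list[str]:
    """Top-N features of each block from a summary_rank-style table."""
    out = []
    for block in ranking["block"].unique():
        sub = ranking[ranking["block"] == block].head(per_block)
        out.extend(sub["feature"].tolist())
    return out
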