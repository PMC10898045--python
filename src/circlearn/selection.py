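"""Ensemble feature selection: seven base rankers aggregated by PageRank.

Each ranker produces a full descending-relevance ordering of the feature
columns.  The orderings are merged into a directed weighted graph — for
every adjacent pair in every ranking, the worse-ranked feature endorses
the better-ranked one — and weighted PageRank over that graph yields the
aggregate score; features are selected in descending PageRank order.

Base rankers: ANOVA F statistic, MRMD (max relevance to the label + max
mean distance to other features), binned mutual information (a proxy for
MIC), L1-regularized logistic regression, MRMR, chi-square, and recursive
feature elimination with a linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE, chi2 as _chi2, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

RANKER_METHODS = ("anova", "mrmd", "mic", "lasso", "mrmr", "chi2", "rfe")


@dataclass(frozen=True)
class RankedFeatures:
    """Per-ranker orderings plus the PageRank-aggregated final ranking."""

    base_rankings: dict[str, tuple[str, ...]]
    pagerank: dict[str, float]
    final_order: tuple[str, ...]
    selected: tuple[str, ...]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def _order_from_scores(names: list[str], scores: np.ndarray) -> tuple[str, ...]:
    """Descending-score order; ties broken by column position (stable)."""
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=0.0)
    idx = np.argsort(-scores, kind="stable")
    return tuple(names[i] for i in idx)


def _binned_mi(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Mutual information with equal-frequency binning of x."""
    if np.all(x == x[0]):
        return 0.0
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    binned = np.searchsorted(np.unique(qs), x)
    return float(mutual_info_score(binned, y))


def base_rank(matrix: pd.DataFrame, labels, method: str,
              seed: int = 0) -> tuple[str, ...]:
    """One full descending-relevance ordering of the feature columns."""
    if method not in RANKER_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; "
                         f"choose from {RANKER_METHODS}")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ranking requires both classes present")
    names = list(matrix.columns)

    if method == "anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores, _ = f_classif(X, y)
        return _order_from_scores(names, scores)

    if method == "chi2":
        Xs = np.apply_along_axis(_minmax, 0, X)
        scores, _ = _chi2(Xs, y)
        return _order_from_scores(names, scores)

    if method == "mic":
        scores = np.array([_binned_mi(X[:, j], y) for j in range(X.shape[1])])
        return _order_from_scores(names, scores)

    if method == "lasso":
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1,
                                             X.std(axis=0))
        clf = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                                 random_state=seed, max_iter=1000)
        clf.fit(Xs, y)
        return _order_from_scores(names, np.abs(clf.coef_[0]))

    if method == "rfe":
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1,
                                             X.std(axis=0))
        est = LogisticRegression(solver="liblinear", random_state=seed,
                                 max_iter=1000)
        step = 1 if X.shape[1] <= 200 else max(1, X.shape[1] // 100)
        rfe = RFE(est, n_features_to_select=1, step=step)
        rfe.fit(Xs, y)
        # ranking_ gives 1 for the last surviving feature; ascending = best first
        return _order_from_scores(names, -rfe.ranking_.astype(float))

    if method == "mrmd":
        # max relevance (|Pearson r| with label) + max mean Euclidean
        # distance to the other features, both min-max normalized
        Xs = np.apply_along_axis(_minmax, 0, X)
        yc = y - y.mean()
        xc = Xs - Xs.mean(axis=0)
        denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
        rel = np.where(denom == 0, 0.0,
                       np.abs(xc.T @ yc) / np.where(denom == 0, 1, denom))
        # pairwise Euclidean distances between feature columns
        sq = (Xs ** 2).sum(axis=0)
        gram = Xs.T @ Xs
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * gram, 0.0)
        mean_dist = np.sqrt(d2).sum(axis=1) / max(X.shape[1] - 1, 1)
        scores = _minmax(rel) + _minmax(mean_dist)
        return _order_from_scores(names, scores)

    # mrmr: greedy max-relevance (binned MI) min-redundancy (|Pearson|)
    rel = np.array([_binned_mi(X[:, j], y) for j in range(X.shape[1])])
    std = X.std(axis=0)
    Xn = (X - X.mean(axis=0)) / np.where(std == 0, 1, std)
    corr = np.abs(Xn.T @ Xn) / X.shape[0]
    corr[:, std == 0] = 0.0
    corr[std == 0, :] = 0.0
    n = X.shape[1]
    selected: list[int] = [int(np.argmax(rel))]
    remaining = set(range(n)) - set(selected)
    while remaining:
        rem = sorted(remaining)
        red = corr[np.ix_(rem, selected)].mean(axis=1)
        scores = rel[rem] - red
        best = rem[int(np.argmax(scores))]
        selected.append(best)
        remaining.discard(best)
    return tuple(names[i] for i in selected)


def build_rank_graph(base_rankings: dict[str, tuple[str, ...]]) -> nx.DiGraph:
    """Directed endorsement graph over features.

    For each ranking, the feature at rank j+1 (worse) points to the
    feature at rank j (better); parallel endorsements accumulate weight.
    """
    if not base_rankings:
        raise ValueError("at least one base ranking required")
    feature_sets = {frozenset(r) for r in base_rankings.values()}
    if len(feature_sets) != 1:
        raise ValueError("base rankings cover different feature sets")
    g = nx.DiGraph()
    g.add_nodes_from(next(iter(base_rankings.values())))
    for ranking in base_rankings.values():
        for better, worse in zip(ranking, ranking[1:]):
            if g.has_edge(worse, better):
                g[worse][better]["weight"] += 1.0
            else:
                g.add_edge(worse, better, weight=1.0)
    return g


def pagerank(graph: nx.DiGraph, damping: float = 0.85, tol: float = 1e-9,
             max_iter: int = 1000) -> dict[str, float]:
    """Weighted PageRank with uniform teleport; dangling mass spread uniformly."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    try:
        return nx.pagerank(graph, alpha=damping, tol=tol, max_iter=max_iter,
                           weight="weight")
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"PageRank failed to converge in {max_iter} iterations") from exc


def select_features(matrix: pd.DataFrame, labels, d: int | str = "auto",
                    seed: int = 0,
                    methods: tuple[str, ...] = RANKER_METHODS,
                    ) -> tuple[RankedFeatures, pd.DataFrame]:
    """Run all base rankers, aggregate with PageRank, keep the top d.

    d = "auto" picks the d maximizing mean 5-fold CV accuracy of a linear
    probe over a geometric grid of candidate sizes.
    """
    rankings = {m: base_rank(matrix, labels, m, seed=seed) for m in methods}
    graph = build_rank_graph(rankings)
    scores = pagerank(graph)
    final_order = tuple(sorted(
        matrix.columns, key=lambda f: (-scores[f], list(matrix.columns).index(f))))
    n_feat = len(final_order)
    if d == "auto":
        d_grid = sorted({min(n_feat, max(1, int(round(n_feat * frac))))
                         for frac in (0.05, 0.1, 0.2, 0.4, 0.7, 1.0)})
        y = np.asarray(labels)
        best_d, best_acc = d_grid[0], -1.0
        for cand in d_grid:
            cols = list(final_order[:cand])
            X = matrix[cols].to_numpy(dtype=float)
            std = X.std(axis=0)
            X = (X - X.mean(axis=0)) / np.where(std == 0, 1, std)
            probe = LogisticRegression(max_iter=1000, random_state=seed)
            cv = StratifiedKFold(5, shuffle=True, random_state=seed)
            acc = cross_val_score(probe, X, y, cv=cv).mean()
            if acc > best_acc + 1e-12:
                best_d, best_acc = cand, acc
        d = best_d
    if d > n_feat:
        warnings.warn(f"d={d} exceeds feature count ({n_feat}); keeping all",
                      stacklevel=2)
        d = n_feat
    selected = final_order[:d]
    ranked = RankedFeatures(base_rankings=rankings, pagerank=dict(scores),
                            final_order=final_order, selected=selected)
    return ranked, matrix[list(selected)]


def ranking_report(ranked: RankedFeatures) -> pd.DataFrame:
    """Tidy report: feature, block prefix, per-ranker rank, PageRank, selected."""
    features = list(ranked.final_order)
    rows = []
    for feat in features:
        prefix = "".join(ch for ch in feat if ch.isalpha())
        row = {"feature": feat, "block": prefix,
               "pagerank": ranked.pagerank[feat],
               "selected": feat in set(ranked.selected)}
        for method, ordering in ranked.base_rankings.items():
            row[f"rank_{method}"] = ordering.index(feat) + 1
        rows.append(row)
    return pd.DataFrame(rows)
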