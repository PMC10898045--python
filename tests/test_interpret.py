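from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from circlearn.interpret import (block_tally, dependence_pair,
                                 shap_for_matrix, shap_values, summary_rank,
                                 top_features_per_block, violin_data)


def brute_force_shapley(f, x, background):
    """Exact Shapley values by averaging marginal contributions over all
    feature orderings, with the conditional value approximated by the
    background-replacement expectation (the same value function the
    estimator targets)."""
    M = len(x)

    def value(subset):
        data = np.array(background, dtype=float, copy=True)
        for j in subset:
            data[:, j] = x[j]
        return float(np.mean(f(data)))

    phi = np.zeros(M)
    perms = list(permutations(range(M)))
    for perm in perms:
        seen = []
        prev = value(seen)
        for j in perm:
            seen.append(j)
            cur = value(seen)
            phi[j] += cur - prev
            prev = cur
    return phi / len(perms)


class TestShapValues:
    def test_linear_model_closed_form(self, rng):
        w = np.array([1.5, -2.0, 0.7, 0.0, 3.0, -0.4])
        f = lambda X: X @ w + 0.3
        background = rng.normal(size=(50, 6))
        X = rng.normal(size=(10, 6))
        attr = shap_values(f, X, background, seed=0)
        expected = w * (X - background.mean(axis=0))
        assert np.allclose(attr.values, expected, atol=1e-3)

    def test_matches_brute_force_enumeration(self, rng):
        """Exact agreement with permutation-enumeration Shapley for a
        nonlinear model of up to 8 features."""
        for M in (3, 5, 8):
            w = rng.normal(size=M)
            f = lambda X: np.tanh(X @ w) + 0.5 * X[:, 0] * X[:, 1]
            background = rng.normal(size=(8, M))
            X = rng.normal(size=(4, M))
            attr = shap_values(f, X, background, seed=0)
            for i in range(len(X)):
                exact = brute_force_shapley(f, X[i], background)
                assert np.allclose(attr.values[i], exact, atol=1e-8)

    def test_additivity(self, rng):
        w = rng.normal(size=5)
        f = lambda X: np.sin(X @ w)
        background = rng.normal(size=(12, 5))
        X = rng.normal(size=(6, 5))
        attr = shap_values(f, X, background, seed=0)
        recon = attr.base_value + attr.values.sum(axis=1)
        assert np.allclose(recon, f(X), atol=1e-8)

    def test_sampled_path_additivity_and_determinism(self, rng):
        """With too many features to enumerate, the sampled estimator still
        satisfies additivity (enforced by the constraint) and is seeded."""
        M = 16
        w = rng.normal(size=M)
        f = lambda X: np.tanh(X @ w)
        background = rng.normal(size=(10, M))
        X = rng.normal(size=(3, M))
        a1 = shap_values(f, X, background, n_samples=512, seed=7)
        a2 = shap_values(f, X, background, n_samples=512, seed=7)
        assert np.array_equal(a1.values, a2.values)
        recon = a1.base_value + a1.values.sum(axis=1)
        assert np.allclose(recon, f(X), atol=1e-2)

    def test_constant_feature_zero_attribution(self, rng):
        f = lambda X: X[:, 0] * 2.0
        background = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        X = np.column_stack([rng.normal(size=5), np.full(5, 3.0)])
        attr = shap_values(f, X, background, seed=0)
        assert np.allclose(attr.values[:, 1], 0.0, atol=1e-10)

    def test_shape_mismatch_and_empty_background(self, rng):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="features"):
            shap_values(f, rng.normal(size=(2, 3)), rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="non-empty"):
            shap_values(f, rng.normal(size=(2, 3)), np.empty((0, 3)))


class TestSummary:
    def _attr(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)),
                         columns=["rcm1", "con1", "seq1", "seq2"])
        w = np.array([5.0, 1.0, 0.5, 0.1])
        f = lambda A: A @ w
        return shap_for_matrix(f, X, X.iloc[:10], seed=0)

    def test_dominant_feature_first_and_tally_partitions(self, rng):
        attr = self._attr(rng)
        summary = summary_rank(attr, top_n=3)
        assert summary["feature"].iloc[0] == "rcm1"
        tally = block_tally(summary)
        assert tally.sum() == 3
        assert set(summary["block"]) <= {"rcm", "con", "seq"}

    def test_zero_attributions_deterministic(self):
        from circlearn.interpret import AttributionMatrix
        attr = AttributionMatrix(values=np.zeros((5, 3)), base_value=0.5,
                                 feature_names=["a", "b", "c"],
                                 feature_values=np.zeros((5, 3)),
                                 model_output=np.full(5, 0.5))
        s1 = summary_rank(attr, top_n=3)
        s2 = summary_rank(attr, top_n=3)
        assert (s1["mean_abs_shap"] == 0).all()
        assert list(s1["feature"]) == list(s2["feature"])

    def test_top_features_per_block(self, rng):
        attr = self._attr(rng)
        summary = summary_rank(attr, top_n=4)
        feats = top_features_per_block(summary, per_block=1)
        assert "rcm1" in feats and len(feats) == 3


class TestDependence:
    def test_planted_interaction_selects_partner(self, rng):
        f = lambda X: X[:, 0] * X[:, 1]
        background = rng.normal(size=(25, 3))
        X = rng.normal(size=(80, 3))
        attr = shap_values(f, X, background, seed=0)
        attr.feature_names = ["x1", "x2", "x3"]
        table = dependence_pair(attr, "x1")
        assert table["color_feature"].iloc[0] == "x2"

    def test_single_feature_degenerate_rule(self, rng):
        f = lambda X: X[:, 0]
        attr = shap_values(f, rng.normal(size=(10, 1)),
                           rng.normal(size=(5, 1)), seed=0)
        attr.feature_names = ["only"]
        assert dependence_pair(attr, "only")["color_feature"].iloc[0] == "only"

    def test_unknown_feature_rejected(self, rng):
        f = lambda X: X.sum(axis=1)
        attr = shap_values(f, rng.normal(size=(5, 2)),
                           rng.normal(size=(5, 2)), seed=0)
        with pytest.raises(KeyError):
            dependence_pair(attr, "nope")


class TestViolin:
    def test_row_count_and_class_coding(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["rcm1", "seq1"])
        y = np.repeat([1, 0], 10)
        table = violin_data(X, y, ["rcm1", "seq1"])
        assert len(table) == 40
        assert set(table["class"]) == {0, 1}
        # positive label (1) maps to figure class "0"
        pos_rows = table[table["class"] == 0]
        assert len(pos_rows) == 20

    def test_separable_feature_has_distinct_class_means(self, rng):
        y = np.repeat([1, 0], 25)
        X = pd.DataFrame({"rcm1": y * 3.0 + rng.normal(0, 0.1, 50)})
        table = violin_data(X, y, ["rcm1"])
        means = table.groupby("class")["value"].mean()
        assert means[0] > means[1] + 2
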