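"""Gradient-boosting components against hand values and a literal oracle."""

import numpy as np
import pytest

from musksynth.gboost import (GBCModel, fit_gbc, fit_regression_tree, gbc_init,
                              gbc_leaf_value, gbc_negative_gradient,
                              gbc_predict_proba)


class TestInit:
    def test_balanced_classes_give_zero(self):
        assert gbc_init([1, 0, 1, 0]) == pytest.approx(0.0)

    def test_log_odds_three_to_one(self):
        assert gbc_init([1, 1, 1, 0]) == pytest.approx(np.log(3.0))
        assert gbc_init([1, 0, 0, 0]) == pytest.approx(-np.log(3.0))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            gbc_init([1, 1, 1])


class TestNegativeGradient:
    def test_symmetric_at_zero_score(self):
        r = gbc_negative_gradient([1, 0], [0.0, 0.0])
        assert r == pytest.approx([0.5, -0.5])

    def test_saturation(self):
        r = gbc_negative_gradient([1, 0], [40.0, -40.0])
        assert abs(r[0]) < 1e-12 and abs(r[1]) < 1e-12

    def test_bounded_open_interval(self):
        rng = np.random.default_rng(0)
        F = rng.normal(0, 5, 100)
        y = rng.integers(0, 2, 100)
        r = gbc_negative_gradient(y, F)
        assert np.all(r > -1) and np.all(r < 1)


class TestLeafValue:
    @pytest.mark.parametrize("r,y,expected", [
        ([0.5], [1], 2.0),
        ([-0.5], [0], -2.0),
        ([0.5, -0.5], [1, 0], 0.0),
    ])
    def test_newton_step_hand_values(self, r, y, expected):
        assert gbc_leaf_value(r, y) == pytest.approx(expected)

    def test_degenerate_denominator_clamped(self, caplog):
        # y=1 with r ~ 0 means p ~ 1: denominator p(1-p) vanishes
        value = gbc_leaf_value([1e-12], [1])
        assert np.isfinite(value)


class TestRegressionTree:
    def test_constant_targets_single_leaf(self):
        tree = fit_regression_tree(np.arange(10).reshape(-1, 1), np.full(10, 3.5))
        assert tree.n_leaves == 1
        assert tree.predict([[0.0]]) == pytest.approx([3.5])

    def test_depth_one_recovers_two_means(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        t = np.array([1.0, 1.2, 0.8, 5.0, 5.2, 4.8])
        tree = fit_regression_tree(X, t, max_depth=1)
        assert tree.predict([[1.0]]) == pytest.approx([1.0])
        assert tree.predict([[11.0]]) == pytest.approx([5.0])

    def test_matches_exhaustive_split_oracle(self):
        """Depth-2 tree equals brute-force search over all candidate splits."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((50, 3))
        t = rng.standard_normal(50)

        def sse(v):
            return float(np.sum((v - v.mean()) ** 2)) if v.size else 0.0

        def best_split(Xs, ts):
            best = (None, None, sse(ts))
            for j in range(Xs.shape[1]):
                for thr in np.unique(Xs[:, j]):
                    m = Xs[:, j] <= thr
                    if m.all() or not m.any():
                        continue
                    cost = sse(ts[m]) + sse(ts[~m])
                    if cost < best[2] - 1e-12:
                        best = (j, thr, cost)
            return best

        def oracle_predict(Xs, ts, x, depth):
            if depth == 0 or np.ptp(ts) == 0:
                return ts.mean()
            j, thr, _ = best_split(Xs, ts)
            if j is None:
                return ts.mean()
            m = Xs[:, j] <= thr
            side = m if x[j] <= thr else ~m
            return oracle_predict(Xs[side], ts[side], x, depth - 1)

        tree = fit_regression_tree(X, t, max_depth=2)
        got = tree.predict(X)
        want = np.array([oracle_predict(X, t, x, 2) for x in X])
        assert got == pytest.approx(want, abs=1e-10)


def literal_boosting_oracle(X, y, M, max_depth):
    """Straight transcription of the update equations with shrinkage 1.

    F0 = log(p/(1-p)); r_i = y_i - 1/(1+exp(-F_i)); leaves of a
    least-squares tree define the regions; c = sum r / sum (y-r)(1-y+r);
    F_m = F_{m-1} + sum_j c_j I(x in R_j).
    """
    y = np.asarray(y, float)
    p = y.mean()
    F = np.full(y.size, np.log(p / (1 - p)))
    history = [F.copy()]
    for _ in range(M):
        r = y - 1.0 / (1.0 + np.exp(-F))
        tree = fit_regression_tree(X, r, max_depth=max_depth)
        leaf = tree.apply(X)
        for lid in np.unique(leaf):
            m = leaf == lid
            c = np.sum(r[m]) / np.sum((y[m] - r[m]) * (1 - y[m] + r[m]))
            F[m] = F[m] + c
        history.append(F.copy())
    return history


class TestBoosting:
    def test_m_zero_predicts_logistic_of_prior(self):
        X = np.random.default_rng(1).standard_normal((8, 2))
        y = [1, 1, 0, 0, 0, 1, 0, 0]
        model = fit_gbc(X, y, M=0)
        want = 1.0 / (1.0 + np.exp(-model.F0))
        assert gbc_predict_proba(model, X)[:, 1] == pytest.approx(np.full(8, want))

    def test_constant_features_predict_base_rate(self):
        X = np.ones((10, 3))
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        model = fit_gbc(X, y, M=25)
        assert gbc_predict_proba(model, X)[:, 1] == pytest.approx(np.full(10, 0.3))

    def test_separable_clusters_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 0.5, (10, 2)), rng.normal(3, 0.5, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        model = fit_gbc(X, y, M=50)
        assert np.array_equal(model.predict(X), y)

    def test_training_deviance_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        y = (X[:, 0] + 0.5 * rng.standard_normal(30) > 0).astype(int)
        model = fit_gbc(X, y, M=40, shrinkage=0.1)
        dev = np.array(model.train_deviance)
        assert np.all(np.diff(dev) <= 1e-12)

    @pytest.mark.parametrize("seed,n,depth", [(0, 12, 1), (1, 20, 1), (2, 16, 2)])
    def test_staged_scores_match_literal_oracle(self, seed, n, depth):
        """With shrinkage 1 the staged F values follow the printed updates."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        y = (rng.random(n) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        M = 6
        model = fit_gbc(X, y, M=M, max_depth=depth, shrinkage=1.0)
        history = literal_boosting_oracle(X, y, M, depth)
        for m in range(M + 1):
            got = model.decision_function(X, n_stages=m)
            assert got == pytest.approx(history[m], abs=1e-10)

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((15, 2))
        y = (X[:, 0] > 0).astype(int)
        proba = fit_gbc(X, y, M=30).predict_proba(X)
        assert np.all(proba > 0) and np.all(proba < 1)
        assert proba.sum(axis=1) == pytest.approx(np.ones(15))
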