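"""Extremely randomized trees (ERT) for binary classification.

Unlike a random forest, every tree sees the full training sample (no
bootstrap); randomization comes entirely from the split search: at each
node ``k_features`` candidate features are drawn and each receives one
uniform-random cut point inside its value range; the candidate with the
largest Gini impurity decrease wins. The ensemble class probability is
the arithmetic mean of the per-tree leaf class frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ERTEnsemble", "fit_ert", "ert_predict_proba", "ensemble_probability"]


@dataclass
class _Node:
    feature: int | None = None
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    proba: float = 0.5  # P(class 1) from leaf class frequencies


class _ExtraTree:
    def __init__(self, root: _Node):
        self.root = root

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.root
            while node.feature is not None:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.proba
        return out


def _gini(y: np.ndarray) -> float:
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _grow(X: np.ndarray, y: np.ndarray, idx: np.ndarray, k: int, min_leaf: int,
          rng: np.random.Generator) -> _Node:
    yi = y[idx]
    if yi.size < 2 * min_leaf or yi.min() == yi.max():
        return _Node(proba=float(yi.mean()))
    # candidate features must be non-constant within the node
    spans = X[idx].max(axis=0) - X[idx].min(axis=0)
    usable = np.flatnonzero(spans > 0)
    if usable.size == 0:
        return _Node(proba=float(yi.mean()))
    feats = rng.choice(usable, size=min(k, usable.size), replace=False)
    parent = _gini(yi)
    best_gain, best_feat, best_thr, best_mask = -1.0, None, 0.0, None
    for j in feats:
        lo, hi = X[idx, j].min(), X[idx, j].max()
        thr = rng.uniform(lo, hi)
        mask = X[idx, j] <= thr
        nl = int(mask.sum())
        if nl < min_leaf or yi.size - nl < min_leaf:
            continue
        child = (nl * _gini(yi[mask]) + (yi.size - nl) * _gini(yi[~mask])) / yi.size
        gain = parent - child
        if gain > best_gain:
            best_gain, best_feat, best_thr, best_mask = gain, int(j), float(thr), mask
    if best_feat is None:
        return _Node(proba=float(yi.mean()))
    return _Node(feature=best_feat, threshold=best_thr,
                 left=_grow(X, y, idx[best_mask], k, min_leaf, rng),
                 right=_grow(X, y, idx[~best_mask], k, min_leaf, rng))


@dataclass
class ERTEnsemble:
    """A forest of extra-trees; probability = mean of tree probabilities."""

    trees: list[_ExtraTree]
    k_features: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p1 = np.mean([t.predict_proba1(X) for t in self.trees], axis=0)
        return np.column_stack([1.0 - p1, p1])


def fit_ert(X, labels, n_trees: int = 100, k_features: int | None = None,
            min_leaf: int = 1, seed: int | None = None) -> ERTEnsemble:
    """Grow ``n_trees`` extra-trees on the full sample (no bootstrap)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("training needs both classes present")
    d = X.shape[1]
    k = k_features if k_features is not None else max(1, int(np.sqrt(d)))
    rng = np.random.default_rng(seed)
    idx = np.arange(y.size)
    trees = [_ExtraTree(_grow(X, y, idx, k, min_leaf, rng)) for _ in range(n_trees)]
    return ERTEnsemble(trees=trees, k_features=k)


def ert_predict_proba(ensemble: ERTEnsemble, X) -> np.ndarray:
    return ensemble.predict_proba(X)


def ensemble_probability(tree_probabilities) -> float:
    """Mean of per-tree class probabilities — the ensemble aggregation rule."""
    p = np.asarray(tree_probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty ensemble")
    return float(p.mean())


class ERTClassifier:
    """sklearn-style wrapper used by the PU bagger."""

    def __init__(self, n_trees: int = 100, k_features: int | None = None,
                 min_leaf: int = 1, random_state: int | None = None):
        self.n_trees = n_trees
        self.k_features = k_features
        self.min_leaf = min_leaf
        self.random_state = random_state
        self.ensemble_: ERTEnsemble | None = None

    def fit(self, X, y):
        self.ensemble_ = fit_ert(X, y, n_trees=self.n_trees, k_features=self.k_features,
                                 min_leaf=self.min_leaf, seed=self.random_state)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.ensemble_ is None:
            raise RuntimeError("classifier is not fitted")
        return self.ensemble_.predict_proba(X)
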