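"""Gradient-boosting classifier built from its update equations.

Binary classification with the binomial deviance loss:

* initialization   F0 = log(p / (1 - p)), p = fraction of positives;
* negative gradient r_i = y_i - 1 / (1 + exp(-F(x_i)));
* a least-squares regression tree fitted to (x_i, r_i) defines the stage's
  leaf regions R_{m,j};
* leaf values are single Newton steps
  c_{m,j} = sum(r_i) / sum((y_i - r_i)(1 - y_i + r_i)), the denominator
  being sum(p_i (1 - p_i)) over the leaf;
* F_m = F_{m-1} + nu * sum_j c_{m,j} I(x in R_{m,j});
* P(Y=1|x) = 1 / (1 + exp(-F_M(x))).

With shrinkage nu = 1 the staged values match the literal update
equations; the default nu = 0.1 is the usual regularized setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionTree",
    "fit_regression_tree",
    "GBCModel",
    "gbc_init",
    "gbc_negative_gradient",
    "gbc_leaf_value",
    "fit_gbc",
    "gbc_predict_proba",
]

#: Magnitude floor for the Newton denominator in degenerate leaves.
LEAF_DENOM_FLOOR = 1e-6


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def gbc_init(labels) -> float:
    """Prior log-odds F0 = log(p / (1 - p)); requires both classes present."""
    y = np.asarray(labels, dtype=float)
    p = y.mean()
    if p <= 0.0 or p >= 1.0:
        raise ValueError("initialization needs both classes present")
    return float(np.log(p / (1.0 - p)))


def gbc_negative_gradient(labels, F) -> np.ndarray:
    """Pseudo-residuals r_i = y_i - sigmoid(F_i), each in (-1, 1)."""
    y = np.asarray(labels, dtype=float)
    F = np.asarray(F, dtype=float)
    if y.shape != F.shape:
        raise ValueError("labels and scores must have equal length")
    return y - _sigmoid(F)


def gbc_leaf_value(residuals, labels) -> float:
    """Newton-step leaf value c = sum(r) / sum((y - r)(1 - y + r)).

    For y in {0, 1} the denominator equals sum(p (1 - p)) with p the
    current predicted probability. A vanishing denominator (pure leaf at
    saturated probabilities) is clamped to +-1e-6 and logged.
    """
    r = np.asarray(residuals, dtype=float)
    y = np.asarray(labels, dtype=float)
    if r.size == 0:
        raise ValueError("empty leaf")
    denom = float(np.sum((y - r) * (1.0 - y + r)))
    if abs(denom) < LEAF_DENOM_FLOOR:
        logger.warning("degenerate leaf denominator %.3g clamped", denom)
        denom = LEAF_DENOM_FLOOR if denom >= 0 else -LEAF_DENOM_FLOOR
    return float(np.sum(r) / denom)


# ---------------------------------------------------------------------------
# least-squares regression tree (axis-aligned, exhaustive split search)
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    feature: int | None = None
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0
    leaf_id: int = -1


class RegressionTree:
    """Binary axis-aligned regression tree, split by squared-error reduction.

    Splits are found by exhaustive search over midpoints of consecutive
    distinct sorted feature values, so on small data the tree equals a
    brute-force oracle over all candidate thresholds.
    """

    def __init__(self, root: _Node, n_leaves: int):
        self.root = root
        self.n_leaves = n_leaves

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self._leaf(row).value for row in X])

    def apply(self, X) -> np.ndarray:
        """Leaf index (region id) for every row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self._leaf(row).leaf_id for row in X], dtype=int)

    def set_leaf_values(self, values: dict[int, float]) -> None:
        for node in self._leaves(self.root):
            node.value = values[node.leaf_id]

    def leaf_ids(self) -> list[int]:
        return [n.leaf_id for n in self._leaves(self.root)]

    def _leaf(self, row: np.ndarray) -> _Node:
        node = self.root
        while node.feature is not None:
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node

    def _leaves(self, node: _Node):
        if node.feature is None:
            yield node
        else:
            yield from self._leaves(node.left)
            yield from self._leaves(node.right)


def _best_split(X: np.ndarray, t: np.ndarray, min_leaf: int):
    """Return (feature, threshold, gain) of the best SSE-reducing split."""
    n = t.size
    base = float(np.sum((t - t.mean()) ** 2))
    best = (None, 0.0, 0.0)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        xs, ts = X[order, j], t[order]
        csum = np.cumsum(ts)
        csum2 = np.cumsum(ts * ts)
        total, total2 = csum[-1], csum2[-1]
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i] == xs[i + 1]:
                continue
            nl = i + 1
            nr = n - nl
            sse_l = csum2[i] - csum[i] ** 2 / nl
            sse_r = (total2 - csum2[i]) - (total - csum[i]) ** 2 / nr
            gain = base - (sse_l + sse_r)
            if gain > best[2] + 1e-12:
                best = (j, float((xs[i] + xs[i + 1]) / 2.0), float(gain))
    return best


def fit_regression_tree(X, targets, max_depth: int = 3, min_leaf: int = 1) -> RegressionTree:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(targets, dtype=float)
    if t.size < 2 * min_leaf:
        # not enough samples to split at all -> single leaf
        root = _Node(value=float(t.mean()), leaf_id=0)
        return RegressionTree(root, 1)
    counter = {"n": 0}

    def build(idx: np.ndarray, depth: int) -> _Node:
        ti = t[idx]
        if depth >= max_depth or ti.size < 2 * min_leaf or np.ptp(ti) == 0.0:
            node = _Node(value=float(ti.mean()), leaf_id=counter["n"])
            counter["n"] += 1
            return node
        feat, thr, gain = _best_split(X[idx], ti, min_leaf)
        if feat is None or gain <= 0.0:
            node = _Node(value=float(ti.mean()), leaf_id=counter["n"])
            counter["n"] += 1
            return node
        mask = X[idx, feat] <= thr
        return _Node(feature=feat, threshold=thr,
                     left=build(idx[mask], depth + 1),
                     right=build(idx[~mask], depth + 1))

    root = build(np.arange(t.size), 0)
    return RegressionTree(root, counter["n"])


# ---------------------------------------------------------------------------
# boosting
# ---------------------------------------------------------------------------

@dataclass
class GBCModel:
    """Fitted boosted classifier: F0 plus M shrunken regression-tree stages."""

    F0: float
    stages: list[RegressionTree]
    shrinkage: float
    train_deviance: list[float] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.stages)

    def decision_function(self, X, n_stages: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = self.M if n_stages is None else n_stages
        F = np.full(X.shape[0], self.F0)
        for tree in self.stages[:m]:
            F += self.shrinkage * tree.predict(X)
        return F

    def predict_proba(self, X) -> np.ndarray:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    # sklearn-compatible alias used by the PU bagger
    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _deviance(y: np.ndarray, F: np.ndarray) -> float:
    # mean binomial deviance, numerically safe via logaddexp
    return float(np.mean(np.logaddexp(0.0, -(2.0 * y - 1.0) * F)))


def fit_gbc(X, labels, M: int = 100, max_depth: int = 3, shrinkage: float = 0.1,
            min_leaf: int = 1, seed: int | None = None) -> GBCModel:
    """Fit the boosted classifier; training is deterministic (the split
    search is exhaustive), so ``seed`` only exists for interface symmetry
    with the randomized learners."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=float)
    F0 = gbc_init(y)
    F = np.full(y.size, F0)
    stages: list[RegressionTree] = []
    deviance = [_deviance(y, F)]
    for _ in range(M):
        r = gbc_negative_gradient(y, F)
        tree = fit_regression_tree(X, r, max_depth=max_depth, min_leaf=min_leaf)
        leaf_of = tree.apply(X)
        values = {leaf: gbc_leaf_value(r[leaf_of == leaf], y[leaf_of == leaf])
                  for leaf in np.unique(leaf_of)}
        # leaves never reached by training data keep their mean-residual value
        for leaf in tree.leaf_ids():
            values.setdefault(leaf, 0.0)
        tree.set_leaf_values(values)
        F = F + shrinkage * tree.predict(X)
        stages.append(tree)
        deviance.append(_deviance(y, F))
    return GBCModel(F0=F0, stages=stages, shrinkage=shrinkage, train_deviance=deviance)


def gbc_predict_proba(model: GBCModel, X) -> np.ndarray:
    return model.predict_proba(X)


class GBCClassifier:
    """Thin sklearn-style wrapper so the PU bagger can treat GBC uniformly."""

    def __init__(self, M: int = 100, max_depth: int = 3, shrinkage: float = 0.1,
                 min_leaf: int = 1, random_state: int | None = None):
        self.M = M
        self.max_depth = max_depth
        self.shrinkage = shrinkage
        self.min_leaf = min_leaf
        self.random_state = random_state
        self.model_: GBCModel | None = None

    def fit(self, X, y):
        self.model_ = fit_gbc(X, y, M=self.M, max_depth=self.max_depth,
                              shrinkage=self.shrinkage, min_leaf=self.min_leaf,
                              seed=self.random_state)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return self.model_.predict_proba(X)
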