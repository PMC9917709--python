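"""Transductive bagging positive-unlabeled (PU) learning.

Only 11 of the 88 molecules carry a definite label (they were actually
synthesized and commercialized); the other 77 designed derivatives are
unlabeled, not negative. Following the bagging-PU scheme of Mordelet &
Vert, each of T iterations draws a random subset of K unlabeled
molecules, provisionally treats it as the negative class, trains a base
classifier against the positives and records the predicted class-1
probability for every molecule *outside* that training set. A molecule's
synthesizability is the average of its out-of-bag predictions; positives
(always in-bag) are scored by averaging all T classifiers. "Relabeling"
is the per-iteration random draw — labels are never mutated persistently.

Defaults follow the published protocol: T = 23 iterations, K = number of
positives, decision threshold 0.5 (inclusive: published score tables list
molecules at exactly 0.50 as synthesizable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exttrees import ERTClassifier
from .gboost import GBCClassifier
from .io_tables import DescriptorTable, ScoreTable

__all__ = ["PUConfig", "PUResult", "BaggingPUModel", "fit_bagging_pu", "validation_stats"]

DEFAULT_ITERATIONS = 23
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class PUConfig:
    """Bagging-PU hyper-parameters.

    ``bootstrap_size`` (K) defaults to the number of positives, balancing
    the provisional training classes. ``with_replacement`` switches the
    unlabeled draw to sampling with replacement (out-of-bag semantics are
    cleaner without it, which is the default).
    """

    n_iterations: int = DEFAULT_ITERATIONS
    bootstrap_size: int | None = None
    threshold: float = DEFAULT_THRESHOLD
    base_learner: str = "rf"
    learner_params: dict = field(default_factory=dict)
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.base_learner not in ("rf", "ert", "gbc"):
            raise ValueError(f"unknown base learner {self.base_learner!r}")


@dataclass
class PUResult:
    """Per-molecule synthesizability scores plus ensemble diagnostics."""

    scores: dict[str, float]
    oob_counts: dict[str, int]
    evaluation_score: float
    config: PUConfig
    positive_ids: list[str]

    def score_table(self) -> ScoreTable:
        return ScoreTable(self.config.base_learner, dict(self.scores))

    def synthesizable_ids(self, threshold: float | None = None) -> set[str]:
        tau = self.config.threshold if threshold is None else threshold
        return {i for i, s in self.scores.items() if s >= tau and i not in set(self.positive_ids)}

    def summary(self) -> str:
        pos = set(self.positive_ids)
        unl = [i for i in self.scores if i not in pos]
        synth = self.synthesizable_ids()
        lines = [
            "Transductive bagging-PU results",
            "=" * 46,
            f"base learner:        {self.config.base_learner}",
            f"iterations (T):      {self.config.n_iterations}",
            f"negatives/iter (K):  {self.config.bootstrap_size}",
            f"molecules:           {len(self.scores)} "
            f"({len(pos)} positive, {len(unl)} unlabeled)",
            f"evaluation score:    {self.evaluation_score:.3f}",
            f"synthesizable (score >= {self.config.threshold}): {len(synth)} unlabeled",
            "-" * 46,
            "top unlabeled molecules:",
        ]
        top = sorted(unl, key=lambda i: -self.scores[i])[:10]
        for i in top:
            lines.append(f"  {i:>8s}  {self.scores[i]:.2f}")
        return "\n".join(lines)


class BaggingPUModel:
    """Model object: a descriptor table plus a PU configuration.

    ``fit()`` runs the bagging loop and returns a :class:`PUResult`.
    """

    def __init__(self, table: DescriptorTable, config: PUConfig | None = None):
        self.table = table
        config = config or PUConfig()
        n_pos = len(table.positive_ids)
        n_unl = len(table.unlabeled_ids)
        if n_pos < 1 or n_unl < 2:
            raise ValueError("need at least 1 positive and 2 unlabeled molecules")
        if config.bootstrap_size is None:
            config = replace(config, bootstrap_size=n_pos)
        if config.bootstrap_size > n_unl and not config.with_replacement:
            raise ValueError("bootstrap_size exceeds the number of unlabeled molecules")
        self.config = config

    @classmethod
    def from_dataframe(cls, frame, label_column: str = "label",
                       config: PUConfig | None = None) -> "BaggingPUModel":
        from .io_tables import MoleculeRecord
        import pandas as pd

        frame = frame.copy()
        labels = frame.pop(label_column).astype(int)
        molecules = [MoleculeRecord(str(i), "positive" if l == 1 else "unlabeled")
                     for i, l in labels.items()]
        values = frame.astype(float)
        values.index = pd.Index([str(i) for i in frame.index], name="molecule_id")
        return cls(DescriptorTable(molecules, values), config)

    def _make_learner(self, sub_seed: int):
        params = dict(self.config.learner_params)
        if self.config.base_learner == "rf":
            from sklearn.ensemble import RandomForestClassifier

            params.setdefault("n_estimators", 100)
            params.setdefault("max_features", "sqrt")
            params.setdefault("criterion", "gini")
            return RandomForestClassifier(random_state=sub_seed, **params)
        if self.config.base_learner == "ert":
            return ERTClassifier(random_state=sub_seed, **params)
        return GBCClassifier(random_state=sub_seed, **params)

    def fit(self) -> PUResult:
        cfg = self.config
        table = self.table
        X = table.X
        ids = table.ids
        labels = table.labels
        pos_idx = np.flatnonzero(labels == 1)
        unl_idx = np.flatnonzero(labels == 0)
        K = cfg.bootstrap_size

        acc = np.zeros(len(ids))
        oob = np.zeros(len(ids), dtype=int)
        pos_acc = np.zeros(len(ids))

        for t in range(cfg.n_iterations):
            # per-iteration substream: stable under changes to T
            ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(t,))
            rng = np.random.default_rng(ss)
            drawn = rng.choice(unl_idx, size=K, replace=cfg.with_replacement)
            train = np.concatenate([pos_idx, drawn])
            y_train = np.concatenate([np.ones(pos_idx.size), np.zeros(drawn.size)])
            sub_seed = int(rng.integers(0, 2**31 - 1))
            learner = self._make_learner(sub_seed).fit(X[train], y_train)
            proba = learner.predict_proba(X)[:, 1]
            out_of_bag = np.setdiff1d(unl_idx, drawn, assume_unique=False)
            acc[out_of_bag] += proba[out_of_bag]
            oob[out_of_bag] += 1
            pos_acc[pos_idx] += proba[pos_idx]

        never_oob = [ids[i] for i in unl_idx if oob[i] == 0]
        if never_oob:
            raise RuntimeError(
                f"molecules never out-of-bag: {never_oob}; increase n_iterations "
                f"or decrease bootstrap_size")

        scores: dict[str, float] = {}
        for i in pos_idx:
            scores[ids[i]] = float(pos_acc[i] / cfg.n_iterations)
        for i in unl_idx:
            scores[ids[i]] = float(acc[i] / oob[i])
        oob_counts = {ids[i]: int(oob[i]) for i in range(len(ids))}

        # agreement between thresholded averaged predictions and the
        # training labels (positives -> 1, unlabeled -> 0)
        predicted = np.array([scores[i] >= cfg.threshold for i in ids], dtype=int)
        evaluation = float(np.mean(predicted == labels))
        return PUResult(scores=scores, oob_counts=oob_counts,
                        evaluation_score=evaluation, config=cfg,
                        positive_ids=list(table.positive_ids))


def fit_bagging_pu(table: DescriptorTable, config: PUConfig | None = None) -> PUResult:
    """Functional entry point over :class:`BaggingPUModel`."""
    return BaggingPUModel(table, config).fit()


def validation_stats(observed, predicted, baseline_mean: float | None = None) -> dict[str, float]:
    """Generic regression validation statistics (R^2, q^2, SEE, r^2_pred).

    ``q2`` applies the PRESS/SStot definition: pass leave-one-out
    predictions to obtain q^2_LOO, fitted values to obtain R^2 (the two
    share one formula with different inputs). ``r2_pred`` normalizes the
    prediction error by spread around ``baseline_mean`` (the training-set
    mean for an external test set; defaults to the observed mean).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance")
    ss_res = float(np.sum((o - p) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    base = o.mean() if baseline_mean is None else float(baseline_mean)
    ss_base = float(np.sum((o - base) ** 2))
    r2_pred = 1.0 - ss_res / ss_base if ss_base > 0 else float("nan")
    see = float(np.sqrt(ss_res / (o.size - 2)))
    return {"R2": r2, "q2": r2, "SEE": see, "r2_pred": r2_pred}
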