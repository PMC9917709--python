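"""Pearson-correlation dimensionality reduction of a descriptor table.

Redundant descriptors are pruned by a greedy left-to-right scan: a column
is dropped iff its absolute Pearson correlation with an already-retained
column exceeds the threshold (0.6 by default, the "strong correlation"
boundary). The earlier column of a violating pair is kept, which makes
the result deterministic and reproducible; an alternative rule keeps the
higher-variance member. The retained set can depend on column order —
this is a documented property of the greedy rule, not a defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import DescriptorTable

__all__ = ["ReductionResult", "pearson_r", "correlation_matrix", "reduce_descriptors"]

DEFAULT_THRESHOLD = 0.6


@dataclass
class ReductionResult:
    """Outcome of the greedy pruning scan.

    ``dropped`` lists, for each eliminated descriptor, the retained partner
    it violated the threshold with and their correlation at drop time.
    """

    retained: list[str]
    dropped: list[tuple[str, str, float]]
    correlation_matrix: np.ndarray
    descriptor_names: list[str]
    threshold: float = DEFAULT_THRESHOLD

    def apply(self, table: DescriptorTable) -> DescriptorTable:
        return table.subset_descriptors(self.retained)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length, non-constant vectors.

    r = sum((x - xbar)(y - ybar)) / sqrt(sum((x - xbar)^2) sum((y - ybar)^2))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r needs two 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("pearson_r needs at least two observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(dx @ dy / np.sqrt(sx * sy))


def correlation_matrix(table: DescriptorTable) -> np.ndarray:
    """Symmetric descriptor-by-descriptor Pearson matrix with unit diagonal."""
    X = table.X
    stds = X.std(axis=0)
    if np.any(stds == 0.0):
        names = [n for n, s in zip(table.descriptor_names, stds) if s == 0.0]
        raise ValueError(f"constant descriptor columns (clean the table first): {names}")
    if np.isnan(X).any():
        raise ValueError("missing values present; clean the table first")
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def reduce_descriptors(table: DescriptorTable,
                       threshold: float = DEFAULT_THRESHOLD) -> ReductionResult:
    """Greedy scan in column order, dropping any column with |r| > threshold
    against an already-retained column.

    The first column is always retained, so the result is never empty.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    names = table.descriptor_names
    corr = correlation_matrix(table)
    retained_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(names)):
        violator = None
        for i in retained_idx:
            if abs(corr[i, j]) > threshold:
                violator = i
                break
        if violator is None:
            retained_idx.append(j)
        else:
            dropped.append((names[j], names[violator], float(corr[violator, j])))
    return ReductionResult(
        retained=[names[j] for j in retained_idx],
        dropped=dropped,
        correlation_matrix=corr,
        descriptor_names=names,
        threshold=threshold,
    )
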