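"""Linear 2D-QSAR mechanism analysis of synthesizability.

Workflow: rank the retained descriptors by absolute Pearson correlation
with the synthesizability scores, regress the scores on the top
descriptors by ordinary least squares, then probe the fitted linear
model with one-at-a-time perturbations to obtain sensitivity
coefficients

    SC_i = (dY / Y) / (dX_i / X_i),

evaluated at the per-descriptor sample mean with each descriptor
inflated by 10%..50% of its baseline value. Two denominator conventions
are supported and reported explicitly, because they behave differently
for a linear model:

* ``base``: Y in the denominator is the unperturbed prediction; SC is
  then independent of the perturbation fraction (closed form
  |b_i X_i / Y(X)|).
* ``perturbed`` (default): Y is the perturbed prediction; SC then drifts
  with the perturbation fraction, which is the only convention under
  which the growth-rate analysis of the coefficients is non-trivial.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_tables import DescriptorTable
from .reduce import pearson_r
from .screen import round_half_up

__all__ = [
    "LinearQsarModel",
    "SensitivityReport",
    "rank_descriptors",
    "fit_linear_model",
    "sensitivity_coefficients",
    "growth_rates",
    "load_formula_models",
]

DEFAULT_DELTAS = (0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass
class LinearQsarModel:
    """Intercept + per-descriptor coefficients; prediction is exactly linear."""

    intercept: float
    coefficients: dict[str, float]
    fit_stats: dict[str, float] | None = None
    std_errors: dict[str, float] | None = None

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, values: Mapping[str, float] | pd.DataFrame) -> float | np.ndarray:
        if isinstance(values, pd.DataFrame):
            X = values[self.descriptor_names].to_numpy(dtype=float)
            b = np.array([self.coefficients[n] for n in self.descriptor_names])
            return self.intercept + X @ b
        return self.intercept + sum(self.coefficients[n] * float(values[n])
                                    for n in self.descriptor_names)

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearQsarModel":
        return cls(intercept=float(d["intercept"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()})

    def summary(self) -> str:
        lines = ["Linear QSAR model", "-" * 38,
                 f"{'intercept':<14s} {self.intercept:>12.5f}"]
        for name, b in self.coefficients.items():
            se = ""
            if self.std_errors and name in self.std_errors:
                se = f"  (se {self.std_errors[name]:.4f})"
            lines.append(f"{name:<14s} {b:>12.5f}{se}")
        if self.fit_stats:
            lines.append("-" * 38)
            for k, v in self.fit_stats.items():
                lines.append(f"{k:<14s} {v:>12.5f}")
        return "\n".join(lines)


def rank_descriptors(table: DescriptorTable, target) -> list[tuple[str, float]]:
    """Descriptors sorted by descending |Pearson r| with the target scores.

    This is the univariate scoring behind SelectKBest-style filtering
    (|r| is monotone in the univariate F statistic for a fixed sample
    size). Constant descriptors are excluded with a warning.
    """
    y = np.asarray(target, dtype=float)
    if y.size != table.n_molecules:
        raise ValueError("target length does not match the table")
    ranked = []
    for name in table.descriptor_names:
        col = table.values[name].to_numpy(dtype=float)
        if np.ptp(col) == 0.0:
            warnings.warn(f"constant descriptor {name!r} excluded from ranking")
            continue
        ranked.append((name, abs(pearson_r(col, y))))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked


def fit_linear_model(X: pd.DataFrame, y) -> LinearQsarModel:
    """OLS of synthesizability on the chosen descriptors (statsmodels).

    fit_stats carries R (multiple correlation), R^2, the F-test p-value
    and the standard error of estimate; std_errors carries per-coefficient
    standard errors for parameter-recovery checks.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of descriptors + 1")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    coef = {name: float(res.params[name]) for name in X.columns}
    ses = {name: float(res.bse[name]) for name in X.columns}
    ses["const"] = float(res.bse["const"])
    stats = {
        "R": float(np.sqrt(max(res.rsquared, 0.0))),
        "R2": float(res.rsquared),
        "F_pvalue": float(res.f_pvalue),
        "SEE": float(np.sqrt(res.mse_resid)),
    }
    return LinearQsarModel(intercept=float(res.params["const"]), coefficients=coef,
                           fit_stats=stats, std_errors=ses)


@dataclass
class SensitivityReport:
    """|SC| on a perturbation grid, with signs kept alongside."""

    baseline: dict[str, float]
    grid: dict[tuple[str, float], float]          # (descriptor, delta) -> |SC|
    signed_grid: dict[tuple[str, float], float]   # (descriptor, delta) -> SC
    deltas: tuple[float, ...]
    convention: str

    def sc(self, name: str, delta: float) -> float:
        return self.grid[(name, delta)]


def sensitivity_coefficients(model: LinearQsarModel, baseline: Mapping[str, float],
                             deltas: Sequence[float] = DEFAULT_DELTAS,
                             convention: str = "perturbed") -> SensitivityReport:
    """One-at-a-time perturbation sensitivities of a linear QSAR model.

    For descriptor i and fraction delta, x_i is inflated to
    x_i * (1 + delta); SC = |dY / Y_den| / delta with Y_den the baseline
    prediction (``base``) or the perturbed prediction (``perturbed``).
    """
    if convention not in ("base", "perturbed"):
        raise ValueError("convention must be 'base' or 'perturbed'")
    base_point = {n: float(baseline[n]) for n in model.descriptor_names}
    y0 = float(model.predict(base_point))
    grid: dict[tuple[str, float], float] = {}
    signed: dict[tuple[str, float], float] = {}
    for name in model.descriptor_names:
        for delta in deltas:
            point = dict(base_point)
            point[name] = base_point[name] * (1.0 + delta)
            y1 = float(model.predict(point))
            y_den = y0 if convention == "base" else y1
            if y_den == 0.0:
                raise ZeroDivisionError(
                    f"prediction is zero at the evaluation point for {name!r}")
            sc = ((y1 - y0) / y_den) / delta
            grid[(name, delta)] = abs(sc)
            signed[(name, delta)] = sc
    return SensitivityReport(baseline=base_point, grid=grid, signed_grid=signed,
                             deltas=tuple(deltas), convention=convention)


def growth_rates(report: SensitivityReport) -> dict[str, dict[str, float]]:
    """Percent growth of |SC| between consecutive perturbation fractions.

    Band growth = 100 * (SC(d2) - SC(d1)) / SC(d1); the per-descriptor
    average is the mean of the bands. Percentages are half-up rounded to
    two decimals.
    """
    deltas = report.deltas
    names = sorted({n for n, _ in report.grid})
    out: dict[str, dict[str, float]] = {}
    for name in names:
        bands: dict[str, float] = {}
        values = []
        for d1, d2 in zip(deltas[:-1], deltas[1:]):
            s1 = report.grid[(name, d1)]
            s2 = report.grid[(name, d2)]
            if s1 == 0.0:
                raise ZeroDivisionError(f"SC({name}, {d1}) is zero")
            g = 100.0 * (s2 - s1) / s1
            bands[f"{d1:.0%}-{d2:.0%}"] = round_half_up(g)
            values.append(g)
        bands["average"] = round_half_up(float(np.mean(values)))
        out[name] = bands
    return out


def load_formula_models() -> dict[str, LinearQsarModel]:
    """The three published linear QSAR models (one per base learner)."""
    text = resources.files("musksynth.data").joinpath("linear_qsar_formulas.json").read_text()
    return {k: LinearQsarModel.from_dict(v) for k, v in json.loads(text).items()}
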