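"""Intramolecular hydrogen-bond strength analysis.

A C-H...O contact counts as a hydrogen bond when the H...A distance is
below 3.2 angstroms. The bond energy E_HB (kcal/mol, negative) is
estimated from the electron density rho at the AIM bond critical point
through a linear calibration E_HB = slope * rho + intercept; the
calibration is fitted by least squares to (rho, E_HB) pairs rather than
hard-coded, and agrees with the published neutral-system relation
(~ -223.08 rho + 0.7423) when fitted to the packaged bond table.

Strength classes: "very weak" above -2.5 kcal/mol, "weak to medium"
between -14 and -2.5 (boundary inclusive on the weak side), "strong" at
or below -14.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_tables import HBondRecord
from .screen import round_half_up

__all__ = [
    "HBondRecord",
    "HBCalibration",
    "is_hbond",
    "fit_calibration",
    "estimate_ehb",
    "classify_hb_strength",
    "formation_rate",
    "weak_bond_fraction",
    "bond_counts",
]

HBOND_LENGTH_CUTOFF = 3.2   # angstrom, strict
VERY_WEAK_BOUNDARY = -2.5   # kcal/mol
STRONG_BOUNDARY = -14.0     # kcal/mol
CALIBRATION_RANGE = (0.0, 0.05)  # a.u., validity range of the linear map


@dataclass
class HBCalibration:
    """Linear map E_HB = slope * rho + intercept (kcal/mol vs a.u.)."""

    slope: float
    intercept: float
    fit_rmse: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative "
                             "(denser BCP = stronger bond)")


def is_hbond(length_ha: float, cutoff: float = HBOND_LENGTH_CUTOFF) -> bool:
    """Geometric criterion: H...A distance strictly below the cutoff."""
    if length_ha <= 0:
        raise ValueError("H...A length must be positive")
    return length_ha < cutoff


def fit_calibration(records: Iterable[HBondRecord] | Sequence[tuple[float, float]]
                    ) -> HBCalibration:
    """Least-squares line through (rho_bcp, E_HB) pairs.

    Accepts HBondRecords (with e_hb set) or raw (rho, e_hb) tuples;
    needs at least 3 points spanning a density range.
    """
    pairs = []
    for r in records:
        if isinstance(r, HBondRecord):
            if r.e_hb is None:
                raise ValueError(f"record {r.molecule_id} {r.path} has no E_HB")
            pairs.append((r.rho_bcp, r.e_hb))
        else:
            pairs.append((float(r[0]), float(r[1])))
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration points")
    rho = np.array([p[0] for p in pairs])
    e = np.array([p[1] for p in pairs])
    if np.ptp(rho) == 0.0:
        raise ValueError("degenerate density spread")
    A = np.column_stack([rho, np.ones_like(rho)])
    (slope, intercept), *_ = np.linalg.lstsq(A, e, rcond=None)
    resid = e - (slope * rho + intercept)
    return HBCalibration(slope=float(slope), intercept=float(intercept),
                         fit_rmse=float(np.sqrt(np.mean(resid**2))),
                         n_points=len(pairs))


def estimate_ehb(rho_bcp: float, calibration: HBCalibration) -> float:
    """E_HB from the BCP density; warns when extrapolating beyond (0, 0.05] a.u."""
    lo, hi = CALIBRATION_RANGE
    if not (lo < rho_bcp <= hi):
        warnings.warn(f"rho = {rho_bcp} a.u. outside the calibration range "
                      f"({lo}, {hi}]; extrapolating")
    return calibration.slope * rho_bcp + calibration.intercept


def classify_hb_strength(e_hb: float) -> str:
    """Strength class from E_HB; the -2.5 boundary belongs to weak_to_medium."""
    if e_hb >= 0:
        raise ValueError("E_HB of a bound hydrogen bond must be negative")
    if e_hb > VERY_WEAK_BOUNDARY:
        return "very_weak"
    if e_hb > STRONG_BOUNDARY:
        return "weak_to_medium"
    return "strong"


def bond_counts(records: Iterable[HBondRecord]) -> dict[str, int]:
    """Number of recorded hydrogen bonds per molecule."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.molecule_id] = counts.get(r.molecule_id, 0) + 1
    return counts


def formation_rate(records: Iterable[HBondRecord], group: set[str] | Sequence[str]) -> float:
    """Percent of molecules in the group with at least one hydrogen bond."""
    group = set(group)
    if not group:
        raise ValueError("empty molecule group")
    with_bonds = {r.molecule_id for r in records} & group
    return round_half_up(100.0 * len(with_bonds) / len(group))


def weak_bond_fraction(records: Iterable[HBondRecord],
                       group: set[str] | Sequence[str]) -> float:
    """Percent of the group's bonds classified weak_to_medium.

    Classification uses the recorded E_HB when present, otherwise it must
    be estimated beforehand (records with e_hb None raise).
    """
    group = set(group)
    bonds = [r for r in records if r.molecule_id in group]
    if not bonds:
        raise ValueError("group has no recorded bonds")
    classes = []
    for r in bonds:
        if r.e_hb is None:
            raise ValueError(f"bond {r.molecule_id} {r.path} has no E_HB; "
                             f"estimate it from the calibration first")
        classes.append(classify_hb_strength(r.e_hb))
    weak = sum(c == "weak_to_medium" for c in classes)
    return round_half_up(100.0 * weak / len(bonds))
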