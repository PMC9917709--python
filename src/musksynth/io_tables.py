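"""Tabular containers, CSV/JSON readers and writers, and packaged fixtures.

Every stage of the screening pipeline exchanges data through the types
defined here: a molecule-by-descriptor matrix with positive/unlabeled
roles (:class:`DescriptorTable`), per-model synthesizability scores
(:class:`ScoreTable`), parent/derivative endpoint scores
(:class:`EndpointTable`) and intramolecular hydrogen-bond records
(:class:`HBondRecord`).

Column conventions (single source of truth):

* id column ``molecule_id``; label column ``label`` with 1 = positive
  (commercialized musk) and 0 = unlabeled (designed derivative);
* missing descriptor values are empty cells; missingness drops the whole
  descriptor column, never the molecule;
* Unicode minus signs (U+2212) are normalized to ASCII hyphens on read so
  published tables paste in directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ID_COLUMN = "molecule_id"
LABEL_COLUMN = "label"

__all__ = [
    "MoleculeRecord",
    "DescriptorTable",
    "ScoreTable",
    "EndpointTable",
    "HBondRecord",
    "read_descriptor_table",
    "clean_descriptors",
    "read_score_table",
    "write_score_table",
    "read_endpoint_table",
    "write_endpoint_table",
    "read_hbond_table",
    "write_hbond_table",
    "write_report",
    "read_report",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_table5",
    "load_table8",
    "load_table8_groups",
    "load_table11",
    "load_retained_descriptors",
]

#: Signed docking/toxicity endpoints and which direction is an improvement.
ENDPOINT_DIRECTIONS = {
    "1A52": "lower_better",    # estrogen receptor docking: abortion risk
    "1A28": "lower_better",    # progesterone receptor docking: abortion risk
    "4ZRY": "lower_better",    # skin keratin docking: bioaccumulation
    "OR5AN1": "higher_better",  # olfactory receptor docking: odor sensitivity
    "LC50": "higher_better",    # fish LC50: higher concentration = less toxic
}


@dataclass
class MoleculeRecord:
    """One molecule: a commercial musk (positive) or a designed derivative."""

    id: str
    role: str  # "positive" | "unlabeled"
    parent_id: str | None = None
    display_name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("positive", "unlabeled"):
            raise ValueError(f"unknown role {self.role!r} for molecule {self.id!r}")


class DescriptorTable:
    """Molecules x named real descriptors with positive/unlabeled roles.

    Wraps a :class:`pandas.DataFrame` indexed by molecule id. Missing
    entries (NaN) are allowed until :func:`clean_descriptors` is applied.
    """

    def __init__(self, molecules: Sequence[MoleculeRecord], values: pd.DataFrame,
                 units: Mapping[str, str] | None = None):
        ids = [m.id for m in molecules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate molecule ids: {dupes}")
        if list(values.index) != ids:
            raise ValueError("values index does not match molecule ids")
        known = set(ids)
        for m in molecules:
            if m.parent_id is not None and m.parent_id not in known:
                raise ValueError(f"parent_id {m.parent_id!r} of {m.id!r} not in table")
        self.molecules = list(molecules)
        self.values = values.astype(float)
        self.units = dict(units or {})

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """1 for positives, 0 for unlabeled, in table order."""
        return np.array([1 if m.role == "positive" else 0 for m in self.molecules])

    @property
    def positive_ids(self) -> list[str]:
        return [m.id for m in self.molecules if m.role == "positive"]

    @property
    def unlabeled_ids(self) -> list[str]:
        return [m.id for m in self.molecules if m.role == "unlabeled"]

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(self.molecules, self.values.loc[:, list(names)],
                               {k: v for k, v in self.units.items() if k in set(names)})

    # -- round trip ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, LABEL_COLUMN, self.labels)
        out.index.name = ID_COLUMN
        out.to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"DescriptorTable({self.n_molecules} molecules "
                f"[{len(self.positive_ids)} positive], {self.n_descriptors} descriptors)")


@dataclass
class ScoreTable:
    """Per-molecule synthesizability scores from one bagging-PU model."""

    model_name: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.scores.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(f"scores outside [0, 1]: {bad}")

    def series(self) -> pd.Series:
        return pd.Series(self.scores, name=self.model_name)


class EndpointTable:
    """Parent/derivative endpoint scores (docking, LC50) in long form.

    Columns: molecule_id, parent_id (empty for parents), endpoint, value.
    Every derivative row must have a parent row for the same endpoint.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {ID_COLUMN, "parent_id", "endpoint", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["parent_id"] = frame["parent_id"].fillna("").astype(str)
        unknown = set(frame["endpoint"]) - set(ENDPOINT_DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown endpoints: {sorted(unknown)}")
        for _, row in frame[frame["parent_id"] != ""].iterrows():
            match = (frame[ID_COLUMN] == row["parent_id"]) & (frame["endpoint"] == row["endpoint"])
            if not match.any():
                raise ValueError(
                    f"derivative {row[ID_COLUMN]!r} has no parent row "
                    f"({row['parent_id']!r}, {row['endpoint']!r})")
        self.frame = frame.reset_index(drop=True)

    @property
    def parents(self) -> list[str]:
        return sorted(self.frame.loc[self.frame["parent_id"] == "", ID_COLUMN].unique())

    @property
    def derivatives(self) -> list[str]:
        return sorted(self.frame.loc[self.frame["parent_id"] != "", ID_COLUMN].unique())

    def value(self, molecule_id: str, endpoint: str) -> float:
        sel = self.frame[(self.frame[ID_COLUMN] == molecule_id)
                         & (self.frame["endpoint"] == endpoint)]
        if sel.empty:
            raise KeyError(f"no {endpoint!r} row for {molecule_id!r}")
        return float(sel["value"].iloc[0])

    def parent_of(self, molecule_id: str) -> str:
        sel = self.frame[(self.frame[ID_COLUMN] == molecule_id) & (self.frame["parent_id"] != "")]
        if sel.empty:
            raise KeyError(f"{molecule_id!r} is not a derivative in this table")
        return str(sel["parent_id"].iloc[0])

    def endpoints_of(self, molecule_id: str) -> list[str]:
        return list(self.frame.loc[self.frame[ID_COLUMN] == molecule_id, "endpoint"])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class HBondRecord:
    """One intramolecular hydrogen bond D-H...A with its AIM descriptors.

    ``length_ha`` is the H...A distance in angstroms, ``rho_bcp`` the
    electron density at the bond critical point in atomic units and
    ``e_hb`` the estimated bond energy in kcal/mol (negative = bound).
    """

    molecule_id: str
    donor: str
    hydrogen: str
    acceptor: str
    length_ha: float
    rho_bcp: float
    e_hb: float | None = None
    strength_class: str | None = None

    def __post_init__(self) -> None:
        if self.length_ha <= 0:
            raise ValueError(f"non-positive H...A length for {self.molecule_id}")
        if self.rho_bcp <= 0:
            raise ValueError(f"non-positive BCP density for {self.molecule_id}")
        if self.e_hb is not None and self.e_hb >= 0:
            raise ValueError(f"reported E_HB must be negative, got {self.e_hb}")

    @property
    def path(self) -> str:
        return f"{self.donor}-{self.hydrogen}...{self.acceptor}"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _normalize_minus(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.replace("−", "-", regex=True)


def read_descriptor_table(path: str | Path, label_column: str = LABEL_COLUMN,
                          id_column: str = ID_COLUMN) -> DescriptorTable:
    """Read a descriptor CSV: one id column, one 0/1 label column, numeric rest.

    Rows and columns are preserved in file order. Blank cells become NaN
    and are removed later by :func:`clean_descriptors`.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = _normalize_minus(frame)
    for col in (id_column, label_column):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    ids = frame[id_column].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule ids in {path}: {dupes}")
    roles = []
    for i, token in zip(ids, frame[label_column]):
        if token not in ("0", "1"):
            raise ValueError(f"unknown label token {token!r} for molecule {i!r}")
        roles.append("positive" if token == "1" else "unlabeled")
    desc_cols = [c for c in frame.columns if c not in (id_column, label_column)]
    values = frame[desc_cols].replace("", np.nan)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric descriptor cell in {path}: {exc}") from exc
    values.index = pd.Index(ids, name=ID_COLUMN)
    molecules = [MoleculeRecord(i, r) for i, r in zip(ids, roles)]
    return DescriptorTable(molecules, values)


def clean_descriptors(table: DescriptorTable) -> DescriptorTable:
    """Drop every descriptor with any missing value, then every constant one.

    Mirrors the screening protocol: descriptors are eliminated, molecules
    never are. Dropped names are logged at INFO level.
    """
    values = table.values
    with_missing = [c for c in values.columns if values[c].isna().any()]
    kept = values.drop(columns=with_missing)
    constant = [c for c in kept.columns if kept[c].nunique(dropna=False) <= 1]
    kept = kept.drop(columns=constant)
    if with_missing:
        logger.info("dropped %d descriptors with missing values: %s ...",
                    len(with_missing), with_missing[:10])
    if constant:
        logger.info("dropped %d constant descriptors: %s ...", len(constant), constant[:10])
    if kept.shape[1] == 0:
        raise ValueError("cleaning removed every descriptor column")
    return DescriptorTable(table.molecules, kept, table.units)


def read_score_table(path: str | Path, model_name: str,
                     score_column: str = "synthesizability") -> ScoreTable:
    frame = _normalize_minus(pd.read_csv(path, dtype={ID_COLUMN: str}))
    if ID_COLUMN not in frame.columns or score_column not in frame.columns:
        raise ValueError(f"score table {path} needs columns {ID_COLUMN!r}, {score_column!r}")
    ids = frame[ID_COLUMN].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate molecule ids in {path}")
    return ScoreTable(model_name, dict(zip(ids, frame[score_column].astype(float))))


def write_score_table(scores: ScoreTable, path: str | Path) -> None:
    pd.DataFrame({ID_COLUMN: list(scores.scores),
                  "synthesizability": list(scores.scores.values())}).to_csv(path, index=False)


def read_endpoint_table(path: str | Path) -> EndpointTable:
    frame = _normalize_minus(pd.read_csv(path, dtype={ID_COLUMN: str, "parent_id": str},
                                         keep_default_na=False))
    frame["value"] = frame["value"].astype(float)
    return EndpointTable(frame)


def write_endpoint_table(table: EndpointTable, path: str | Path) -> None:
    table.to_csv(path)


def read_hbond_table(path: str | Path) -> list[HBondRecord]:
    """Read hydrogen-bond records; E_HB and printed strength are optional."""
    frame = _normalize_minus(pd.read_csv(path, dtype=str, keep_default_na=False))
    required = [ID_COLUMN, "donor", "hydrogen", "acceptor", "length_angstrom", "rho_bcp_au"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"hbond table {path} missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        try:
            e_hb = float(row["ehb_kcalmol"]) if row.get("ehb_kcalmol", "") != "" else None
            rec = HBondRecord(
                molecule_id=row[ID_COLUMN], donor=row["donor"], hydrogen=row["hydrogen"],
                acceptor=row["acceptor"], length_ha=float(row["length_angstrom"]),
                rho_bcp=float(row["rho_bcp_au"]), e_hb=e_hb,
                strength_class=row.get("printed_strength") or None)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed hbond row {dict(row)}: {exc}") from exc
        records.append(rec)
    return records


def write_hbond_table(records: Iterable[HBondRecord], path: str | Path) -> None:
    rows = [{ID_COLUMN: r.molecule_id, "donor": r.donor, "hydrogen": r.hydrogen,
             "acceptor": r.acceptor, "length_angstrom": r.length_ha,
             "rho_bcp_au": r.rho_bcp, "ehb_kcalmol": "" if r.e_hb is None else r.e_hb,
             "printed_strength": r.strength_class or ""} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(report: Mapping, path: str | Path) -> None:
    """Write a JSON report; nested numpy scalars are converted to floats."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=default))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# packaged fixtures (published score / endpoint / hydrogen-bond tables)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("musksynth.data").joinpath(name)


def load_table1() -> ScoreTable:
    """77 bagging-RF synthesizability scores."""
    return read_score_table(_data_path("table1_rf_scores.csv"), "rf")


def load_table2() -> ScoreTable:
    """77 bagging-ERT synthesizability scores."""
    return read_score_table(_data_path("table2_ert_scores.csv"), "ert")


def load_table3() -> ScoreTable:
    """77 bagging-GBC synthesizability scores."""
    return read_score_table(_data_path("table3_gbc_scores.csv"), "gbc")


def load_table5() -> EndpointTable:
    """Endpoint scores for 4 parent musks and 7 screened derivatives."""
    return read_endpoint_table(_data_path("table5_endpoints.csv"))


def load_table8() -> pd.DataFrame:
    """Key-descriptor values (energy gap, qH+, dipole moment, E_HOMO)."""
    frame = pd.read_csv(_data_path("table8_key_descriptors.csv"), dtype={ID_COLUMN: str})
    return frame.set_index(ID_COLUMN)


def load_table8_groups() -> dict[str, list[str]]:
    """Molecule ids per group: synthesizable / non_synthesizable / positive."""
    frame = load_table8()
    return {g: list(sub.index) for g, sub in frame.groupby("group", sort=False)}


def load_table11() -> list[HBondRecord]:
    """26 intramolecular hydrogen bonds across 7 musk derivatives."""
    return read_hbond_table(_data_path("table11_hbonds.csv"))


def load_retained_descriptors() -> list[str]:
    """The 16 descriptor names retained by the published Pearson pruning."""
    return json.loads(_data_path("retained_descriptors.json").read_text())
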