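"""Shared fixtures: small synthetic tables built at test time."""

import numpy as np
import pandas as pd
import pytest

from musksynth.io_tables import DescriptorTable, MoleculeRecord
from musksynth.synthdata import SynthConfig, generate_descriptor_table


def make_table(values: np.ndarray, labels, names=None, ids=None) -> DescriptorTable:
    """Build a DescriptorTable from a raw matrix and 0/1 labels."""
    n, d = values.shape
    names = names or [f"x{j}" for j in range(d)]
    ids = ids or [f"M{i}" for i in range(n)]
    molecules = [MoleculeRecord(i, "positive" if l == 1 else "unlabeled")
                 for i, l in zip(ids, labels)]
    frame = pd.DataFrame(values, columns=names, index=pd.Index(ids, name="molecule_id"))
    return DescriptorTable(molecules, frame)


@pytest.fixture(scope="session")
def separable_table():
    """Small, strongly separable PU table: 1 signal descriptor, effect 5.

    Correlation pruning is applied first, as in the screening pipeline,
    so the PU learner sees the block representatives.
    """
    from musksynth.io_tables import clean_descriptors
    from musksynth.reduce import reduce_descriptors

    cfg = SynthConfig(seed=7, effect_size=5.0, n_signal=1, n_descriptors=12,
                      n_blocks=4, n_molecules=40, n_positive=6)
    table, truth = generate_descriptor_table(cfg)
    table = clean_descriptors(table)
    return reduce_descriptors(table).apply(table), truth


@pytest.fixture(scope="session")
def default_table():
    """One default-condition synthetic table with its truth labels."""
    return generate_descriptor_table(SynthConfig(seed=11))
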