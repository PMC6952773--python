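import numpy as np
import pandas as pd
import pytest

from triomix.preprocess import OmicsLayer
from triomix.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset for mapping-oracle and round-trip tests."""
    return simulate_dataset(
        SimulationConfig(seed=11, n_genes=80, n_metabolites=20, n_pathways=6)
    )


def make_metadata(n_replicates=5):
    rows = [
        (f"{g}_{c}_r{r + 1}", g, c)
        for g in ("fetal", "adult_male", "adult_female")
        for c in ("normoxia", "hypoxia")
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "condition"])


def make_layer(tag, matrix, sample_ids, feature_ids=None, unique_peptides=None):
    feature_ids = feature_ids or [f"f{i:03d}" for i in range(matrix.shape[0])]
    values = pd.DataFrame(np.asarray(matrix, dtype=float), index=feature_ids,
                          columns=sample_ids)
    up = None
    if unique_peptides is not None:
        up = pd.Series(unique_peptides, index=values.index)
    return OmicsLayer(tag, values, up)
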