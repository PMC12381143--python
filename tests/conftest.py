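import numpy as np
import pandas as pd
import pytest

from stratomics.containers import OmicsMatrix
from stratomics.simulate import (
    SimConfig,
    simulate_reference_tables,
    simulate_sorting_experiment,
    simulate_spatial_omics,
)


def make_matrix(values, kind="protein_log2", compartments=None, fractions=None,
                replicates=None):
    """Small OmicsMatrix builder for hand-written fixtures."""
    values = pd.DataFrame(values)
    n = values.shape[1]
    values.columns = [f"s{i}" for i in range(n)]
    values.index = [f"g{i}" for i in range(values.shape[0])]
    compartments = compartments or ["SO"] * (n // 2) + ["SP"] * (n - n // 2)
    fractions = fractions or ["tissue"] * n
    replicates = replicates or [i + 1 for i in range(n)]
    meta = pd.DataFrame({"compartment": compartments, "replicate": replicates,
                         "fraction": fractions}, index=values.columns)
    return OmicsMatrix(values, kind, meta)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=250, seed=13)


@pytest.fixture(scope="session")
def tissue_bundle(small_config):
    return simulate_spatial_omics(small_config)


@pytest.fixture(scope="session")
def sorting_bundle(small_config):
    return simulate_sorting_experiment(small_config)


@pytest.fixture(scope="session")
def reference_bundle(small_config, tissue_bundle):
    _rna, _prot, truth = tissue_bundle
    return simulate_reference_tables(small_config, truth)
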