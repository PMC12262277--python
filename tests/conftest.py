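import numpy as np
import pandas as pd
import pytest

from melspat import (CellTable, TissueSimConfig, assign_tumor_states,
                     call_phenotypes, rescale_table, simulate_tissue,
                     true_gates)


def make_cell_table(coords, labels=None, specimen="S1", marker_values=None,
                    label_col="phenotype"):
    """Minimal cell table from an (n, 2) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    data = pd.DataFrame({"cell_id": np.arange(len(coords)),
                         "specimen_id": specimen,
                         "x": coords[:, 0], "y": coords[:, 1],
                         "M1": 1.0 if marker_values is None else marker_values})
    if labels is not None:
        data[label_col] = np.asarray(labels, dtype=object)
    return CellTable(data, ["M1"])


@pytest.fixture(scope="session")
def small_tissue():
    """One simulated tissue shared across tests (seed fixed)."""
    config = TissueSimConfig(seed=11, theta=0.4)
    cells, regions, truth = simulate_tissue(config)
    return config, cells, regions, truth


@pytest.fixture(scope="session")
def phenotyped_tissue(small_tissue):
    config, cells, regions, truth = small_tissue
    table = rescale_table(cells, true_gates(config))
    table = call_phenotypes(table)
    table = assign_tumor_states(table)
    return config, table, regions, truth
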