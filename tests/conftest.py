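import numpy as np
import pandas as pd
import pytest

from uromir.expression_io import DatasetCollection, HarmonizedDataset


def make_dataset(dataset_id, genes, case, control):
    """HarmonizedDataset from per-group value matrices (genes x samples)."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    case_ids = [f"{dataset_id}_ca{j}" for j in range(case.shape[1])]
    control_ids = [f"{dataset_id}_co{j}" for j in range(control.shape[1])]
    values = pd.DataFrame(np.hstack([case, control]), index=list(genes),
                          columns=case_ids + control_ids)
    return HarmonizedDataset(dataset_id, values, case_ids, control_ids)


def make_collection(datasets, compartment="glomerulus"):
    genes = list(datasets[0].values.index)
    return DatasetCollection(compartment=compartment, gene_universe=genes,
                             datasets=list(datasets))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
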