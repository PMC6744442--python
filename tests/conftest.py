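import numpy as np
import pandas as pd
import pytest

from famcontent import synthetic
from famcontent.pipeline import PipelineConfig, run_synthetic_pipeline


@pytest.fixture(scope="session")
def default_truth():
    return synthetic.default_truth(seed=1)


@pytest.fixture(scope="session")
def default_world(default_truth):
    matrix, taxonomy = synthetic.generate_presence_matrix(default_truth)
    return default_truth, matrix, taxonomy


@pytest.fixture(scope="session")
def pipeline_result():
    """One end-to-end run of the default planted scenario, shared by tests."""
    return run_synthetic_pipeline(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def sequence_world():
    truth = synthetic.default_sequence_truth(seed=3)
    records = synthetic.generate_sequence_families(truth)
    m8, profiles = synthetic.generate_hit_tables(truth, records, noise=0.0)
    return truth, records, m8, profiles


def toy_matrix(rows, genome_ids=None, family_ids=None):
    """Boolean matrix from a list of 0/1 row tuples."""
    arr = np.asarray(rows, dtype=bool)
    if genome_ids is None:
        genome_ids = [f"g{i+1}" for i in range(arr.shape[0])]
    if family_ids is None:
        family_ids = [f"f{j+1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genome_ids, columns=family_ids)
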