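import numpy as np
import pandas as pd
import pytest

import stagecluster as sc


def make_count_matrix(counts, stages, tissue="SR", batches=None, sample_ids=None):
    """Build a CountMatrix from a 2D array and per-sample stage labels."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "tissue": tissue,
            "stage": list(stages),
            "batch": list(batches) if batches is not None else "b1",
            "replicate": range(1, n + 1),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    frame = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=sample_ids,
    )
    return sc.CountMatrix(counts=frame, sample_meta=meta)


@pytest.fixture(scope="session")
def small_config():
    return sc.SimConfig(
        n_genes=300,
        tissues=("SR", "FR"),
        replicates_per_stage=4,
        modules_per_tissue=2,
        module_size=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return sc.generate_counts(small_config)
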