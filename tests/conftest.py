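import numpy as np
import pandas as pd
import pytest

import hubgene as hg


@pytest.fixture(scope="session")
def small_mesh():
    return hg.gen_surface(4, 100, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """15 subjects, 100 nodes, 8-node fully connected planted core."""
    subjects, truth = hg.gen_cohort_connectomes(
        15, n_nodes=100, core_size=8, distance_decay=10.0, core_boost=1e6,
        subject_noise=0.1, seed=3,
    )
    return subjects, truth


@pytest.fixture(scope="session")
def small_expression():
    """60 genes x 27 regions x 5 zones x 4 specimens, ~15% planted."""
    regions = [f"R{i:02d}" for i in range(27)]
    degree = pd.Series(np.linspace(60, 250, 27), index=regions)
    df, truth = hg.gen_expression_dataset(degree, n_genes=60, seed=5)
    return df, truth, degree
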