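import logging

import numpy as np
import pandas as pd
import pytest

from hnbglm import CountTable, SimConfig, sim_dataset

# the EM max-iter warning is expected on a few hard synthetic replicates
logging.getLogger("hnbglm").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_replicate():
    """Well-conditioned replicate: n=200, 5 covariates, one large effect."""
    return sim_dataset(SimConfig(n=200, k=5, rho_class="weak",
                                 effects={1: "large"}, seed=42))


@pytest.fixture
def wide_replicate():
    """k = n replicate where only the hierarchical model is identifiable."""
    return sim_dataset(SimConfig(n=50, k=50, rho_class="weak", seed=7))


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[30, 40, 25], [5, 0, 3], [0, 0, 0], [65, 60, 72]],
        index=["otu_a", "otu_b", "otu_c", "otu_d"],
        columns=["s1", "s2", "s3"],
    )
    return CountTable.from_frame(counts)
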