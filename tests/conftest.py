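import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import minimaxomics as mx
from minimaxomics.datasets import ad_example_frame, ad_example_table

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ad_table():
    """Published ten-pathway Alzheimer's multi-omics p-value table."""
    return ad_example_table()


@pytest.fixture(scope="session")
def ad_frame():
    return ad_example_frame()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_multiomics():
    """Tiny matched three-layer dataset: 20 blocks of 6 genes, 60 samples."""
    return mx.generate_multiomics(
        n_genes=120, samples_per_omics=(60, 60, 60), rho=0.3, overlap=1.0, seed=101
    )


@pytest.fixture(scope="session")
def null_pairs(small_multiomics):
    """(matrix, phenotype) pairs with labels independent of the data."""
    rng = np.random.default_rng(55)
    out = []
    for layer in small_multiomics.layers:
        groups = pd.Series(
            np.where(rng.random(len(layer.sample_ids)) < 0.5, "A", "B"),
            index=layer.sample_ids,
        )
        out.append((layer, mx.Phenotype(groups, kind="binary")))
    return out
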