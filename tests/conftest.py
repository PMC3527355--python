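import numpy as np
import pytest

from dmtaxa import DMParams, TaxaCountTable, dm_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_table():
    """3 samples x 2 taxa, small enough for hand calculation."""
    return TaxaCountTable.from_counts(
        [[10, 0], [0, 10], [5, 5]],
        sample_ids=["s1", "s2", "s3"],
        taxon_labels=["A", "B"],
    )


@pytest.fixture
def oral_like_params():
    """DM parameters in the range typical of oral-site taxa profiles."""
    return DMParams(np.array([0.5, 0.3, 0.2]), 0.05)


@pytest.fixture
def simulated_table(oral_like_params):
    return dm_sample(oral_like_params, 200, 5000, seed=11)
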