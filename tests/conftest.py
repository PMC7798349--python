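import numpy as np
import pandas as pd
import pytest

import bbrnet as b


@pytest.fixture(scope="session")
def small_study():
    """One compact synthetic study shared by read-only tests."""
    return b.generate_study(b.SimulationConfig(seed=7, n_genes_per_species=12))


@pytest.fixture(scope="session")
def small_combined(small_study):
    return b.combined_feature_table(small_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def groups12():
    return pd.Series(
        ["berberine"] * 6 + ["control"] * 6, index=[f"s{i}" for i in range(12)]
    )
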