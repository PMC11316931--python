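import numpy as np
import pandas as pd
import pytest

from hologuild.synthetic import CohortConfig, simulate_feature_tables
from hologuild.tables import FeatureTable


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size cohort used by tests that only need structure."""
    return CohortConfig(n_animals=120, n_variants=400, n_causal_variants=10,
                        n_features_per_layer=(60, 50, 60), n_differential=12,
                        seed=11)


@pytest.fixture(scope="session")
def feature_panel(small_config):
    """(tables, annotations, fcr, truth) for an 18-sample synthetic panel."""
    return simulate_feature_tables(small_config)


@pytest.fixture()
def toy_table():
    """Hand-built 4-feature, 6-sample table with 3 vs 3 groups."""
    samples = [f"s{i}" for i in range(6)]
    ab = pd.DataFrame(
        [[10.0, 12, 11, 2, 1, 3],
         [1, 2, 1, 9, 11, 10],
         [5, 5, 5, 5, 5, 5],
         [0, 0, 1, 0, 2, 0]],
        index=pd.Index([f"f{i}" for i in range(4)], name="feature_id"),
        columns=samples)
    groups = pd.Series(["efficient"] * 3 + ["inefficient"] * 3, index=samples)
    return FeatureTable("MTP", ab, groups)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
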