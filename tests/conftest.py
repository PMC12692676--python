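import numpy as np
import pandas as pd
import pytest

from lipimark.simulate import SyntheticConfig, generate_lipidome
from lipimark.table import FeatureTable


@pytest.fixture(scope="session")
def small_study():
    """A small default-shaped synthetic study shared across tests."""
    cfg = SyntheticConfig(seed=11, n_features=120)
    table, truth = generate_lipidome(cfg)
    return cfg, table, truth


@pytest.fixture()
def tiny_table():
    """Hand-built 4-feature table with two groups and three QC columns."""
    values = pd.DataFrame(
        {
            "A_1": [1e5, 2e5, 3e5, 4e5],
            "A_2": [1.1e5, 2.1e5, 2.9e5, 4.2e5],
            "B_1": [0.9e5, 1.8e5, 3.1e5, 3.9e5],
            "B_2": [1.2e5, 2.2e5, 3.2e5, 4.1e5],
            "QC_1": [1e5, 2e5, 3e5, 4e5],
            "QC_2": [1.02e5, 1.98e5, 3.03e5, 3.97e5],
            "QC_3": [0.99e5, 2.02e5, 2.97e5, 4.04e5],
        },
        index=[f"L{i}" for i in range(1, 5)],
    )
    groups = pd.Series({"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B",
                        "QC_1": "QC", "QC_2": "QC", "QC_3": "QC"})
    return FeatureTable(values, groups)
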