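import numpy as np
import pandas as pd
import pytest

import osadx
from osadx.table import NOMINAL, NUMERIC, LabeledTable


@pytest.fixture(scope="session")
def schema():
    return osadx.default_schema()


@pytest.fixture
def tiny_table():
    """Hand-built 5x3 mixed table with known missing cells."""
    X = pd.DataFrame(
        {
            "a": [2.0, np.nan, 4.0, 1.0, 3.0],
            "b": [0.0, 0.0, 1.0, np.nan, 0.0],
            "c": [10.0, 20.0, 30.0, 40.0, 50.0],
        }
    )
    y = np.array([0, 1, 0, 1, 1])
    return LabeledTable(X, y, (NUMERIC, NOMINAL, NUMERIC), {"b": ["no", "yes"]})


@pytest.fixture(scope="session")
def planted_table(schema):
    """Preprocessed 31-feature table with five strong planted features."""
    config = osadx.GeneratorConfig(
        planted_features=(4, 7, 19, 21, 28),
        effect_sizes=(1.2, 1.2, 1.2, 1.2, 1.2),
        seed=11,
    )
    table = osadx.generate_dataset(schema, config)
    clean, _ = osadx.preprocess(table)
    return clean, osadx.planted_feature_mask(schema, config)


@pytest.fixture(scope="session")
def small6_table(schema):
    """80-row table restricted to 6 features, two of them informative."""
    config = osadx.GeneratorConfig(
        n_samples=80, planted_features=(5, 6), effect_sizes=(2.0, 2.0), seed=7
    )
    table = osadx.generate_dataset(schema, config)
    mask = np.zeros(schema.n_features, dtype=bool)
    mask[[4, 5, 6, 7, 8, 9]] = True
    clean, _ = osadx.preprocess(table.select_features(mask))
    return clean
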