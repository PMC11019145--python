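import numpy as np
import pandas as pd
import pytest

from metabaxes.preprocess import MetaboliteMatrix, PhenotypeTable
from metabaxes.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One small cohort shared by read-only tests."""
    return generate_cohort(
        GeneratorConfig(n_participants=300, n_metabolites=60, seed=7)
    )


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        {
            "m1": [2.0, np.nan, 4.0, 8.0],
            "m2": [1.0, 3.0, 5.0, 7.0],
            "m3": [np.nan, 6.0, 2.0, np.nan],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    return MetaboliteMatrix(values=values)


@pytest.fixture
def tiny_phenotypes():
    values = pd.DataFrame(
        {
            "gait_speed": [1.2, 0.9, 1.5, 1.1],
            "visceral_fat": [100.0, 160.0, 80.0, 120.0],
            "biomarker_log": [2.0, 4.0, 1.0, 8.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    meta = pd.DataFrame(
        {
            "domain": ["physical_function", "adiposity_sarcopenia", "vascular"],
            "adverse": [False, True, False],
            "transform": ["none", "none", "log"],
            "index_to_height": [False, True, False],
        },
        index=values.columns,
    )
    return PhenotypeTable(values=values, meta=meta)


@pytest.fixture
def heights():
    return pd.Series([1.6, 1.7, 1.8, 1.65], index=["p1", "p2", "p3", "p4"])
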