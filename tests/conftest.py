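import numpy as np
import pandas as pd
import pytest

from metanema import datasets, synth


@pytest.fixture(scope="session")
def survey() -> pd.DataFrame:
    return datasets.species_survey()


@pytest.fixture(scope="session")
def partitions() -> pd.DataFrame:
    return datasets.deviance_partition()


@pytest.fixture(scope="session")
def analysis(survey, partitions) -> pd.DataFrame:
    """The 20 analysed species with traits, Moran's I and partition columns."""
    a = datasets.analysis_set().join(partitions, how="inner")
    assert len(a) == 20
    return a


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One default synthetic survey, shared across tests."""
    return synth.generate(synth.SyntheticConfig(seed=2024))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
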