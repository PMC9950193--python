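import numpy as np
import pandas as pd
import pytest

from radonburden.data_model import ERRSpec, ScenarioConfig
from radonburden.model import RadonBurdenModel
from radonburden.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A 6-region configuration: fast but structurally complete."""
    return SyntheticConfig(n_regions=6, seed=42)


@pytest.fixture(scope="session")
def dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Full 20-region dataset at the default study conditions."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def model(dataset):
    return RadonBurdenModel(
        dataset.population,
        dataset.cases,
        dataset.exposure,
        smoking_series=dataset.smoking_series,
        measurements=dataset.measurements,
    )


@pytest.fixture
def scenario16():
    return ScenarioConfig(err_spec=ERRSpec(16.0))
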