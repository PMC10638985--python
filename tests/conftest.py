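import numpy as np
import pytest

from mdcfa import MissingDesign, PopulationModel, generate_dataset


@pytest.fixture(scope="session")
def complete_500x20():
    """One complete study-sized dataset (500 x 20, loading 0.35, median split)."""
    return generate_dataset(PopulationModel(), seed=20260926)


@pytest.fixture(scope="session")
def incomplete_60_in_ten():
    """The hardest missing-data condition: 60% removed in columns 11-20."""
    design = MissingDesign(tuple(range(11, 21)), 0.6, scheme="shared", seed=99)
    return generate_dataset(PopulationModel(), design, seed=20260926)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
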