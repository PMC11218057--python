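import numpy as np
import pytest

from aggdoe.design import FactorSpec, ModelSpec, interaction_model
from aggdoe.simulate import default_truth, paper_shape_design, simulate_campaign


@pytest.fixture(scope="session")
def two_factors():
    return [FactorSpec("A", 0.0, 10.0, "mg/ml"), FactorSpec("B", 0.0, 2.0, "mg/ml")]


@pytest.fixture(scope="session")
def two_factor_model(two_factors):
    return interaction_model(two_factors)


@pytest.fixture(scope="session")
def campaign_design():
    """The study-shaped design: 16 D-optimal runs + 3 center points, 2 batches."""
    return paper_shape_design(seed=0)


@pytest.fixture(scope="session")
def campaign(campaign_design):
    return simulate_campaign(campaign_design, default_truth(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
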