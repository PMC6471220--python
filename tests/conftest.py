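import numpy as np
import pytest

from gmtrial import (
    SimulationConfig,
    build_endpoint_table,
    fit_length_weight,
    generate_reference_dataset,
    generate_substitution_trial,
)


@pytest.fixture(scope="session")
def range_finding_trial():
    """Default dose-series trial: CCD + 6 substitution diets, 3 tanks, 20 fish."""
    return generate_substitution_trial(SimulationConfig(design="range_finding"), seed=7)


@pytest.fixture(scope="session")
def lw_model(range_finding_trial):
    return fit_length_weight(range_finding_trial.fish, day=0)


@pytest.fixture(scope="session")
def endpoint_table(range_finding_trial, lw_model):
    return build_endpoint_table(range_finding_trial, lw_model)


@pytest.fixture(scope="session")
def reference_dataset():
    """Default natural-response-variation trial: 10 varieties x 3 tanks."""
    return generate_reference_dataset(
        SimulationConfig(design="natural_variation"), seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
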