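import warnings

import pytest

from hpcensus.simulate import (
    SimulationConfig,
    make_reference,
    reverse_decoys,
    simulate_psms,
)
from hpcensus.validate import filter_psms, fit_model


@pytest.fixture(scope="session")
def targets():
    return make_reference()


@pytest.fixture(scope="session")
def decoys(targets):
    return reverse_decoys(targets)


@pytest.fixture(scope="session")
def default_psms(targets, decoys):
    """A moderate seeded two-sample simulation shared across tests."""
    config = SimulationConfig(seed=42, n_psms_per_sample=6000)
    return simulate_psms(config, targets, decoys)


@pytest.fixture(scope="session")
def fitted_model(default_psms):
    return fit_model(default_psms)


@pytest.fixture(scope="session")
def validation_results(default_psms, fitted_model):
    return filter_psms(default_psms, fitted_model)


@pytest.fixture(scope="session")
def passing_psms(validation_results):
    return [r.psm for r in validation_results if r.passed]


@pytest.fixture(autouse=True)
def _quiet_multimap_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="peptide .* matches .* multiple positions"
        )
        yield
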