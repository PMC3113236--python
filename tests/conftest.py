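import numpy as np
import pytest

from lvremodel import (
    ModelParameters,
    ScenarioSpec,
    StimulusProfile,
    default_curves,
    default_parameters,
    run_reference_scenarios,
    simulate,
)
from lvremodel.simulation import FAST_SOLVER


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def curves():
    return default_curves()


@pytest.fixture(scope="session")
def median_trajectory(params, curves):
    """Amplitude-30 (median infarct) trajectory with the precise solver."""
    scenario = ScenarioSpec("median", StimulusProfile(amplitude=30.0, peak_day=2.0))
    return simulate(scenario, params, curves)


@pytest.fixture(scope="session")
def scenario_manifest(params, curves):
    """The six-scenario battery with the precise solver."""
    return run_reference_scenarios(params, curves)


@pytest.fixture(scope="session")
def fast_solver():
    return FAST_SOLVER
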