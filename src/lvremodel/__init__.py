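"""Post-infarction left-ventricular remodeling: an ODE model of the balance
between collagen construction (fibroblasts, TGF-beta1) and destruction
(macrophage-derived MMP-9), with scenario simulation, curve calibration and
synthetic validation data."""

__version__ = "0.1.0"

from .params import ModelParameters, ModelState, STATE_COMPONENTS  # noqa: E402
from .core import (  # noqa: E402
    ModelOptions,
    StimulusProfile,
    InterventionSpec,
    myocyte_crowding,
    crowding_fraction,
    timp_inhibition,
    tgf_activation_input,
    rhs,
)
from .curves import (  # noqa: E402
    InteractionCurve,
    InteractionCurveSet,
    default_curves,
    build_curve_set,
)
from .simulation import (  # noqa: E402
    ScenarioSpec,
    SolverSettings,
    Trajectory,
    SimulationError,
    initial_state,
    complex_equilibrium,
    calibrate_baseline_activation,
    homeostatic_offsets,
    simulate,
    peak_metrics,
    normalize_to_baseline,
    reference_scenarios,
    run_reference_scenarios,
)

__all__ = [
    "ModelParameters", "ModelState", "STATE_COMPONENTS",
    "ModelOptions", "StimulusProfile", "InterventionSpec",
    "myocyte_crowding", "crowding_fraction", "timp_inhibition",
    "tgf_activation_input", "rhs",
    "InteractionCurve", "InteractionCurveSet", "default_curves", "build_curve_set",
    "ScenarioSpec", "SolverSettings", "Trajectory", "SimulationError",
    "initial_state", "complex_equilibrium", "calibrate_baseline_activation",
    "homeostatic_offsets", "simulate", "peak_metrics", "normalize_to_baseline",
    "reference_scenarios", "run_reference_scenarios",
    "default_parameters",
]


def default_parameters() -> ModelParameters:
    """Load the shipped default (published) parameter file."""
    from importlib import resources

    from .params import ModelParameters

    ref = resources.files("lvremodel") / "data" / "default_parameters.json"
    with resources.as_file(ref) as path:
        return ModelParameters.from_json(path)
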