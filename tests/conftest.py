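import numpy as np
import pytest

from trunksim.config import RunConfig
from trunksim.dynamics import TrunkDynamics
from trunksim.trunk_model import (NodePointMass, Rod, TrunkStructure,
                                  build_structure)


@pytest.fixture(scope="session")
def default_structure():
    return build_structure()


@pytest.fixture(scope="session")
def default_dynamics(default_structure):
    return TrunkDynamics(default_structure)


@pytest.fixture(scope="session")
def toy_config():
    """Three-section test-scale trunk configuration."""
    return RunConfig(n_sections=3, total_mass=30.0, total_length=0.4112)


@pytest.fixture(scope="session")
def toy_structure(toy_config):
    return build_structure(toy_config)


GRADED_WEIGHTS = np.linspace(0.3, 1.0, 9)  # distal-dominant bend profile


@pytest.fixture(scope="session")
def fitted_b_laws(default_structure, default_dynamics):
    """Stereotypical laws fitted on three synthetic pure-bending trials.

    Shared session-wide: the inverse-dynamics runs dominate the cost.
    """
    from trunksim.pipeline import estimate_trial_forces, fit_laws_from_trials
    from trunksim.synthetic_data import GeneratorSpec, generate_reaching_trial

    estimates = []
    for peak, seed in [(15.0, 1), (30.0, 2), (45.0, 3)]:
        trial, _ = generate_reaching_trial(
            GeneratorSpec(movement_class="B", peak_K=peak, duration=3.0,
                          sample_rate=20, seed=seed,
                          segment_weights=GRADED_WEIGHTS),
            default_structure.config)
        estimates.append(estimate_trial_forces(trial, default_structure,
                                               dyn=default_dynamics))
    laws = fit_laws_from_trials(estimates, movement_class="B")
    return laws, estimates


def make_spring_structure(mass=1.0, k=4.0 * np.pi**2, length=1.0):
    """Two nodes, one rod along X, first node fixed: a 1-DoF oscillator.

    The rod's E and A are chosen so E*A/L0 equals the requested stiffness.
    """
    nodes = [
        NodePointMass(0, 1, "O", mass, np.zeros(3)),
        NodePointMass(1, 2, "O", mass, np.array([length, 0.0, 0.0])),
    ]
    rods = [Rod(0, (0, 1), "longitudinal", length, k * length, 1.0,
                location_index=1, role="O")]
    return TrunkStructure(nodes=nodes, rods=rods, fixed_nodes=frozenset({0}),
                          total_mass=2 * mass, total_length=length,
                          n_sections=2)
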