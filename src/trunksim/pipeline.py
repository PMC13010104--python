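"""End-to-end analysis pipelines.

These helpers chain the package's modules the way a full study runs them:
synthetic (or recorded) trials -> inverse-dynamics force estimation ->
pooled per-class law fitting -> open-loop reaching driven by the fitted
laws.

Two choices make the chain self-consistent.  First, law fitting pairs the
estimated forces with the shapes measured on the *inverse-dynamics
simulation* (not the idealized trial): the laws then describe the model's
own force-shape relation, which is exactly what the reaching controller
inverts, and the weakly force-dependent length direction stays
well-conditioned.  Second, force estimation tracks the outer section nodes
with a blended (increment + clipped feedback) target and starts from the
static equilibrium of the first sample: radial forces are unobservable
from backbone centers alone, the centers' axial position is not directly
controllable near straight configurations, and idealized targets would
otherwise inject a long-ringing initial transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SystemState, Trajectory, TrunkDynamics
from .force_estimation import (ActiveForceHistory, run_inverse,
                               segment_force_summary, trial_node_targets)
from .kinematics import MovementTrial, ShapeSeries
from .reaching import ShapeTarget, measure_shapes, run_reaching
from .stereotypical_laws import LawSet, fit_segment_laws
from .trunk_model import TrunkStructure

__all__ = [
    "TrialEstimate",
    "estimate_trial_forces",
    "fit_laws_from_trials",
    "reaching_target_from_shapes",
    "replicate_trial_with_laws",
]


@dataclass
class TrialEstimate:
    """Inverse-dynamics result of one trial."""

    trial: MovementTrial
    history: ActiveForceHistory
    sim_positions: np.ndarray  # (n_times, n_nodes, 3)
    sim_shapes: ShapeSeries  # measured on the simulated trajectory


def _shapes_of(sim: np.ndarray, structure: TrunkStructure,
               sample_rate: float) -> ShapeSeries:
    rest = structure.rest_positions()
    states = [SystemState((p - rest).ravel(), np.zeros(structure.n_dof),
                          j / sample_rate) for j, p in enumerate(sim)]
    return measure_shapes(Trajectory(states=states, structure=structure))


def estimate_trial_forces(trial: MovementTrial, structure: TrunkStructure,
                          dyn: TrunkDynamics | None = None,
                          tracked_mode: str = "outer",
                          feedback_gain: float = 0.2,
                          jac_refresh: int = 5) -> TrialEstimate:
    """Run inverse dynamics on a trial and measure the simulated shapes."""
    dyn = dyn or TrunkDynamics(structure)
    history, sim = run_inverse(trial, structure, tracked_mode=tracked_mode,
                               dyn=dyn, jac_refresh=jac_refresh,
                               target_mode="blended",
                               feedback_gain=feedback_gain, static_init=True)
    shapes = _shapes_of(sim, structure, trial.sample_rate)
    return TrialEstimate(trial=trial, history=history, sim_positions=sim,
                         sim_shapes=shapes)


def fit_laws_from_trials(estimates: list[TrialEstimate],
                         movement_class: str | None = None) -> LawSet:
    """Pool per-trial force/shape series and fit the per-segment laws.

    The force of interval ``j`` is paired with the shape measured at the
    interval's end, ``t_{j+1}`` (the configuration that force produced).
    """
    Ks, Ls, dfls, frs, fmls = [], [], [], [], []
    for est in estimates:
        fr, dfl, fml = segment_force_summary(est.history)
        Ks.append(est.sim_shapes.K[:, 1:].T)
        Ls.append(est.sim_shapes.L[:, 1:].T)
        dfls.append(dfl)
        frs.append(fr)
        fmls.append(fml)
    return fit_segment_laws(
        np.vstack(Ks), np.vstack(Ls), np.vstack(dfls), np.vstack(frs),
        np.vstack(fmls), movement_class=movement_class,
        provenance={"n_trials": len(estimates)})


def reaching_target_from_shapes(shapes: ShapeSeries,
                                sample_rate: float | None = None) -> ShapeTarget:
    """Build a reaching target from a shape series' first and last sample."""
    T = float(shapes.times[-1] - shapes.times[0])
    if sample_rate is None:
        sample_rate = (len(shapes.times) - 1) / T
    return ShapeTarget(K_ini=shapes.K[:, 0], K_fin=shapes.K[:, -1],
                       L_ini=shapes.L[:, 0], L_fin=shapes.L[:, -1],
                       duration=T, sample_rate=sample_rate)


def replicate_trial_with_laws(trial: MovementTrial, laws: LawSet,
                              structure: TrunkStructure,
                              dyn: TrunkDynamics | None = None,
                              estimate: TrialEstimate | None = None) -> dict:
    """Replicate a reference movement open-loop through the fitted laws.

    The movement's initial and final segment configurations are measured on
    the inverse-dynamics simulation of the trial (``estimate`` is computed
    if not supplied), interpolated as convex combinations, inverted through
    the laws, and fed to the forward model.  The achieved tip-center
    position is scored against the *trial's* final tip position, relative
    to the arc length of the trial's tip path, in percent.
    """
    dyn = dyn or TrunkDynamics(structure)
    if estimate is None:
        estimate = estimate_trial_forces(trial, structure, dyn=dyn)
    target = reaching_target_from_shapes(estimate.sim_shapes,
                                         sample_rate=trial.sample_rate)
    traj, achieved, schedule = run_reaching(target, laws, structure, dyn=dyn)
    tip = structure.node_id(structure.n_sections, "O")
    ref = trial_node_targets(trial, structure)[:, tip, :]
    sim_tip = traj.positions()[-1, tip]
    err = float(np.linalg.norm((sim_tip - ref[-1])[[0, 2]]))
    path = float(np.linalg.norm(np.diff(ref[:, [0, 2]], axis=0), axis=1).sum())
    return dict(tip_error_m=err, tip_path_m=path,
                tip_error_rel_percent=100.0 * err / path if path > 0 else np.nan,
                trajectory=traj, achieved=achieved, schedule=schedule,
                target=target, estimate=estimate)
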