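"""Open-loop reaching controller driven by the stereotypical laws.

Given initial and final per-segment shape targets (curvature and length),
the controller linearly interpolates the shape between the endpoints (a
convex combination in time), inverts the per-segment law system at every
sample to obtain the internal force aggregates, expands them to rod forces
and applies them as piecewise-constant inputs to the forward dynamic model.
No feedback is used: the force schedule is computed entirely from the
commanded shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import SystemState, Trajectory, TrunkDynamics
from .force_estimation import ForceUnknowns, map_unknowns_to_rod_forces
from .kinematics import ShapeSeries, shape_timeseries
from .stereotypical_laws import LawSet, solve_forces_from_shape
from .trunk_model import ROLES, TrunkStructure

__all__ = [
    "ShapeTarget",
    "interpolate_shape",
    "segment_forces_to_rod_forces",
    "run_reaching",
    "sections_from_positions",
]


@dataclass
class ShapeTarget:
    """Initial and final per-segment shape of one reaching movement."""

    K_ini: np.ndarray  # (n_seg,) deg/m
    K_fin: np.ndarray
    L_ini: np.ndarray  # (n_seg,) m
    L_fin: np.ndarray
    duration: float  # s
    sample_rate: float = 100.0  # Hz

    def __post_init__(self):
        for name in ("K_ini", "K_fin", "L_ini", "L_fin"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if np.any(self.L_ini <= 0) or np.any(self.L_fin <= 0):
            raise ValueError("segment lengths must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.K_ini)


def interpolate_shape(target: ShapeTarget) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convex-combination shape interpolation.

    ``K(t_j) = K_ini*(T - t_j)/T + K_fin*t_j/T`` (and likewise for L) at
    ``t_j = j/fs`` for ``0 <= j < T*fs``.  Returns ``(times, K, L)`` with K
    and L of shape (n_segments, n_samples).  A non-integer ``T*fs`` is
    floored with a warning.
    """
    n_exact = target.duration * target.sample_rate
    n = int(np.floor(n_exact + 1e-9))
    if abs(n_exact - n) > 1e-9:
        warnings.warn(f"T*fs = {n_exact} is not an integer; using {n} samples")
    times = np.arange(n) / target.sample_rate
    w = times / target.duration
    K = np.outer(target.K_ini, 1.0 - w) + np.outer(target.K_fin, w)
    L = np.outer(target.L_ini, 1.0 - w) + np.outer(target.L_fin, w)
    return times, K, L


def segment_forces_to_rod_forces(structure: TrunkStructure, dfl: np.ndarray,
                                 fr: np.ndarray, fml: np.ndarray,
                                 fr_split: str | None = None) -> np.ndarray:
    """Per-segment aggregates to the full per-rod active force vector.

    ``FL_dorsal = Fm_L + dFL/2`` on the dorsal longitudinal rod,
    ``FL_ventral = Fm_L - dFL/2`` on the ventral one; ``FR`` is split over
    the distal section's radial rods.  Lateral longitudinal and connective
    rods carry no active force.
    """
    dfl = np.atleast_1d(np.asarray(dfl, float))
    fr = np.atleast_1d(np.asarray(fr, float))
    fml = np.atleast_1d(np.asarray(fml, float))
    unknowns = ForceUnknowns(fml + dfl / 2.0, fml - dfl / 2.0, fr)
    return map_unknowns_to_rod_forces(structure, unknowns, fr_split)


def run_reaching(target: ShapeTarget, laws: LawSet, structure: TrunkStructure,
                 dyn: TrunkDynamics | None = None,
                 state0: SystemState | None = None,
                 include_endpoint: bool = False,
                 settle_duration: float = 2.5,
                 clip_forces: bool = True,
                 rtol: float = 1e-6, atol: float = 1e-9,
                 ) -> tuple[Trajectory, ShapeSeries, np.ndarray]:
    """Simulate one reaching movement under the stereotypical laws.

    For each interpolation sample the per-segment law systems are inverted
    at the commanded (K, L), the forces are expanded to rods and held
    constant over the sampling interval while the dynamic model integrates
    forward.  The force schedule has exactly ``T*fs`` pieces (the
    interpolation never evaluates t = T; ``include_endpoint=True`` appends
    one extra piece at the exact final target).

    When no initial state is given, the trunk is first settled for
    ``settle_duration`` seconds under the initial commanded forces, so the
    movement starts from the gravity-loaded equilibrium of the initial
    shape rather than from the unloaded rest geometry (set
    ``settle_duration=0`` to start at rest).  The commanded (K, L) should
    lie on the model's own force-shape manifold -- e.g. shapes measured on
    an inverse-dynamics simulation -- since the law inversion extrapolates
    poorly in the weakly force-dependent length direction.

    With ``clip_forces`` (default) the commanded rod forces are clamped to
    the actuator range (contraction-only, bounded): the determined law
    system is nearly collinear in the length direction for some segments,
    and its exact solution can demand forces no muscle analogue could
    produce.  ``schedule`` records the applied (clamped) per-segment
    aggregates.

    Returns the trajectory (sampled at the force-update boundaries), the
    shape series measured on the simulated structure, and the commanded
    force schedule as an array of shape (n_pieces, 3, n_segments) ordered
    (dFL, FR, FmL).
    """
    if target.n_segments != structure.n_segments:
        raise ValueError("target segment count does not match the structure")
    dyn = dyn or TrunkDynamics(structure)
    times, K, L = interpolate_shape(target)
    if include_endpoint:
        K = np.column_stack([K, target.K_fin])
        L = np.column_stack([L, target.L_fin])
    n_pieces = K.shape[1]
    dt = 1.0 / target.sample_rate

    if state0 is not None:
        state = state0.copy()
    else:
        state = dyn.rest_state()
        if settle_duration > 0:
            dfl0 = np.zeros(structure.n_segments)
            fr0 = np.zeros(structure.n_segments)
            fml0 = np.zeros(structure.n_segments)
            for s in range(1, structure.n_segments + 1):
                dfl0[s - 1], fr0[s - 1], fml0[s - 1] = solve_forces_from_shape(
                    K[s - 1, 0], L[s - 1, 0], laws, s)
            if clip_forces:
                dfl0, fr0, fml0 = _clip_to_actuators(structure, dfl0, fr0, fml0)
            f0 = segment_forces_to_rod_forces(structure, dfl0, fr0, fml0)
            settled = dyn.integrate(state, f0, (0.0, settle_duration),
                                    t_eval=np.array([settle_duration]),
                                    rtol=rtol, atol=atol)
            state = settled.states[-1]
            state.time = 0.0
    states = [state.copy()]
    schedule = np.zeros((n_pieces, 3, structure.n_segments))
    for j in range(n_pieces):
        dfl = np.zeros(structure.n_segments)
        fr = np.zeros(structure.n_segments)
        fml = np.zeros(structure.n_segments)
        for s in range(1, structure.n_segments + 1):
            dfl[s - 1], fr[s - 1], fml[s - 1] = solve_forces_from_shape(
                K[s - 1, j], L[s - 1, j], laws, s)
        if clip_forces:
            dfl, fr, fml = _clip_to_actuators(structure, dfl, fr, fml)
        schedule[j] = np.stack([dfl, fr, fml])
        rod_forces = segment_forces_to_rod_forces(structure, dfl, fr, fml)
        state = dyn.step(state, rod_forces, dt, rtol=rtol, atol=atol)
        states.append(state)
    traj = Trajectory(states=states, structure=structure)
    achieved = measure_shapes(traj)
    return traj, achieved, schedule


def _clip_to_actuators(structure: TrunkStructure, dfl: np.ndarray,
                       fr: np.ndarray, fml: np.ndarray):
    """Clamp commanded aggregates to the rod actuator range."""
    cfg = structure.config
    lo = cfg.solver.force_bound_lower if cfg else 0.0
    hi = cfg.solver.force_bound if cfg else 5000.0
    fld = np.clip(fml + dfl / 2.0, lo, hi)
    flv = np.clip(fml - dfl / 2.0, lo, hi)
    fr = np.clip(fr, lo, hi)
    return fld - flv, fr, 0.5 * (fld + flv)


def sections_from_positions(structure: TrunkStructure, positions: np.ndarray
                            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Reconstruct section frames (center, rotation) from node positions.

    The dorsal axis is the unit vector from the ventral (Q) to the dorsal
    (P) node, the lateral axis from A to B (orthonormalized), the normal
    their cross product -- mirroring how the cross-section ellipses define
    their frames.
    """
    out = []
    pos = np.asarray(positions, float)
    for s in range(1, structure.n_sections + 1):
        idx = {role: structure.node_id(s, role) for role in ROLES}
        center = pos[idx["O"]]
        e1 = pos[idx["P"]] - pos[idx["Q"]]
        e1 = e1 / np.linalg.norm(e1)
        e2 = pos[idx["B"]] - pos[idx["A"]]
        e2 = e2 - (e2 @ e1) * e1
        e2 = e2 / np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        out.append((center, np.column_stack([e1, e2, e3])))
    return out


def measure_shapes(traj: Trajectory) -> ShapeSeries:
    """Segment shape series measured on a simulated trajectory."""
    from .kinematics import EllipseSection, MovementTrial

    structure = traj.structure
    positions = traj.positions()
    samples = []
    dt = float(traj.times[1] - traj.times[0]) if len(traj.times) > 1 else 1.0
    for t in range(positions.shape[0]):
        frames = sections_from_positions(structure, positions[t])
        rows = []
        for s, (center, R) in enumerate(frames, start=1):
            a = np.linalg.norm(positions[t, structure.node_id(s, "P")] - center)
            b = np.linalg.norm(positions[t, structure.node_id(s, "B")] - center)
            rows.append(EllipseSection.from_rotation(
                s, center, R, (max(a, 1e-9), max(b, 1e-9)), timestamp=t * dt))
        samples.append(rows)
    trial = MovementTrial(sections=samples, sample_rate=1.0 / dt,
                          n_rows=structure.n_sections)
    return shape_timeseries(trial)
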