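"""Inverse dynamics: estimate active rod forces from observed motion.

At each data timestep the active forces are the unknowns of a bounded
nonlinear least-squares problem: integrate the forward model over one
sampling interval with candidate forces held constant, and minimize the
squared discrepancy between the model's node displacements and the observed
ones over the tracked degrees of freedom.  Estimation is sequential with
warm starting from the previous step.

Unknowns are reduced to three per segment for planar movements: the dorsal
and ventral longitudinal rod forces (``FL_dorsal``, ``FL_ventral``) and the
radial force ``FR`` of the segment's distal section, split equally over its
four radial rods.  The lateral longitudinal rods mirror the segment's mean
longitudinal drive (configurable); connective rods are always passive.
Derived per-segment aggregates are the bending drive
``dFL = FL_dorsal - FL_ventral``, the axial drive
``Fm_L = (FL_dorsal + FL_ventral)/2`` and ``FR``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear

from .config import SolverConfig
from .dynamics import IntegrationError, SystemState, TrunkDynamics
from .kinematics import MovementTrial
from .trunk_model import TrunkStructure, section_node_positions_from_ellipse

__all__ = [
    "ForceUnknowns",
    "ActiveForceHistory",
    "map_unknowns_to_rod_forces",
    "tracked_dof_indices",
    "tracking_objective",
    "estimate_step_forces",
    "run_inverse",
    "segment_force_summary",
    "trial_node_targets",
]

_PENALTY = 1e6  # objective value substituted when the integrator fails


@dataclass
class ForceUnknowns:
    """Per-segment force unknowns of one estimation step (N)."""

    fl_dorsal: np.ndarray
    fl_ventral: np.ndarray
    fr: np.ndarray

    def __post_init__(self):
        self.fl_dorsal = np.atleast_1d(np.asarray(self.fl_dorsal, float))
        self.fl_ventral = np.atleast_1d(np.asarray(self.fl_ventral, float))
        self.fr = np.atleast_1d(np.asarray(self.fr, float))
        if not (len(self.fl_dorsal) == len(self.fl_ventral) == len(self.fr)):
            raise ValueError("per-segment force arrays must have equal length")

    @property
    def n_segments(self) -> int:
        return len(self.fl_dorsal)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.fl_dorsal, self.fl_ventral, self.fr])

    @classmethod
    def from_vector(cls, x: np.ndarray, n_segments: int) -> "ForceUnknowns":
        x = np.asarray(x, float)
        return cls(x[:n_segments], x[n_segments : 2 * n_segments], x[2 * n_segments :])

    @classmethod
    def zeros(cls, n_segments: int) -> "ForceUnknowns":
        z = np.zeros(n_segments)
        return cls(z.copy(), z.copy(), z.copy())


@dataclass
class ActiveForceHistory:
    """Estimated force unknowns over a trial, one entry per data interval."""

    times: np.ndarray  # (n_steps,) start time of each interval
    fl_dorsal: np.ndarray  # (n_steps, n_segments)
    fl_ventral: np.ndarray
    fr: np.ndarray
    residual: np.ndarray = field(default=None)  # per-step objective value
    iterations: np.ndarray = field(default=None)
    converged: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.times)
        if self.residual is None:
            self.residual = np.zeros(n)
        if self.iterations is None:
            self.iterations = np.zeros(n, dtype=int)
        if self.converged is None:
            self.converged = np.ones(n, dtype=bool)

    @property
    def n_steps(self) -> int:
        return len(self.times)

    @property
    def n_segments(self) -> int:
        return self.fl_dorsal.shape[1]

    def step(self, j: int) -> ForceUnknowns:
        return ForceUnknowns(self.fl_dorsal[j], self.fl_ventral[j], self.fr[j])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-time, per-segment force table."""
        fr, dfl, fml = segment_force_summary(self)
        rows = []
        for j, t in enumerate(self.times):
            for i in range(self.n_segments):
                rows.append(
                    dict(time=t, segment=i + 1, FR=fr[j, i],
                         FL_dorsal=self.fl_dorsal[j, i],
                         FL_ventral=self.fl_ventral[j, i],
                         dFL=dfl[j, i], FmL=fml[j, i]))
        return pd.DataFrame(rows)


def segment_force_summary(history: ActiveForceHistory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment aggregates ``(FR, dFL, Fm_L)`` of a force history.

    ``dFL = FL_dorsal - FL_ventral`` and
    ``Fm_L = (FL_dorsal + FL_ventral)/2``.
    """
    dfl = history.fl_dorsal - history.fl_ventral
    fml = 0.5 * (history.fl_dorsal + history.fl_ventral)
    return history.fr.copy(), dfl, fml


def map_unknowns_to_rod_forces(structure: TrunkStructure, unknowns: ForceUnknowns,
                               fr_split: str | None = None,
                               lateral_mode: str | None = None) -> np.ndarray:
    """Expand per-segment unknowns into the full per-rod force vector.

    ``FL_dorsal``/``FL_ventral`` load the segment's dorsal (P) and ventral
    (Q) longitudinal rods; ``FR`` of segment i loads the radial rods of its
    distal section i+1 -- split equally over all four by default, or over
    the dorso-ventral pair only when ``fr_split='dorso-ventral'``.

    The two lateral longitudinal rods carry a common mirrored force equal
    to ``Fm_L`` of their segment when ``lateral_mode='mirrored'`` (the
    default): planar movements drive both trunk sides with the same axial
    effort, and without it the lateral columns hang entirely on passive
    elasticity and sag away from the planar motion.
    ``lateral_mode='passive'`` leaves them unactuated.  Connective rods are
    always passive.
    """
    if fr_split is None:
        fr_split = structure.config.fr_split if structure.config else "four-way"
    if lateral_mode is None:
        lateral_mode = (structure.config.lateral_longitudinal
                        if structure.config else "mirrored")
    if unknowns.n_segments != structure.n_segments:
        raise ValueError(
            f"{unknowns.n_segments} segments of unknowns for a structure "
            f"with {structure.n_segments}")
    f = np.zeros(structure.n_rods)
    for seg in range(1, structure.n_segments + 1):
        f[structure.rod_id("longitudinal", seg, "P")] = unknowns.fl_dorsal[seg - 1]
        f[structure.rod_id("longitudinal", seg, "Q")] = unknowns.fl_ventral[seg - 1]
        if lateral_mode == "mirrored":
            fml = 0.5 * (unknowns.fl_dorsal[seg - 1] + unknowns.fl_ventral[seg - 1])
            f[structure.rod_id("longitudinal", seg, "B")] = fml
            f[structure.rod_id("longitudinal", seg, "A")] = fml
        section = seg + 1
        if fr_split == "four-way":
            for role in ("P", "B", "Q", "A"):
                f[structure.rod_id("radial", section, role)] = unknowns.fr[seg - 1] / 4.0
        else:
            for role in ("P", "Q"):
                f[structure.rod_id("radial", section, role)] = unknowns.fr[seg - 1] / 2.0
    return f


def tracked_dof_indices(structure: TrunkStructure, mode: str = "centers",
                        planar: bool = True) -> np.ndarray:
    """DoF indices compared in the tracking objective.

    ``mode='centers'`` follows the backbone (section-center nodes);
    ``mode='all'`` tracks every free node, which is required for full
    identifiability of the per-segment unknowns (center motion alone carries
    no first-order information about the radial forces) and is appropriate
    for targets generated by the forward model itself; ``mode='outer'``
    tracks the four outer nodes of each section only, which is the right
    choice for idealized kinematic targets: near a straight configuration
    the radial rods are perpendicular to the backbone, so the model has no
    axial force authority over the center nodes and demanding their exact
    position is infeasible (they sag slightly instead).  Planar trials
    track X and Z only.
    """
    if mode == "centers":
        nodes = [nd.node_id for nd in structure.nodes
                 if nd.role == "O" and nd.node_id not in structure.fixed_nodes]
    elif mode == "all":
        nodes = [nd.node_id for nd in structure.nodes
                 if nd.node_id not in structure.fixed_nodes]
    elif mode == "outer":
        nodes = [nd.node_id for nd in structure.nodes
                 if nd.role != "O" and nd.node_id not in structure.fixed_nodes]
    else:
        raise ValueError(f"unknown tracking mode {mode!r}")
    coords = (0, 2) if planar else (0, 1, 2)
    return np.array([3 * n + c for n in nodes for c in coords])


def _step_residuals(x: np.ndarray, dyn: TrunkDynamics, state: SystemState,
                    target_disp: np.ndarray, dt: float, tracked: np.ndarray,
                    solver: SolverConfig) -> np.ndarray:
    unknowns = ForceUnknowns.from_vector(x, dyn.structure.n_segments)
    forces = map_unknowns_to_rod_forces(dyn.structure, unknowns)
    try:
        end = dyn.step(state, forces, dt, rtol=solver.rtol, atol=solver.atol)
    except IntegrationError as exc:
        warnings.warn(f"integration failed during force estimation: {exc}")
        return np.full(len(tracked) + len(x), np.sqrt(_PENALTY / len(tracked)))
    dq = end.q - state.q
    resid = (dq - target_disp)[tracked]
    ridge = np.sqrt(solver.ridge) * (x - solver.tonus) / solver.force_bound
    return np.concatenate([resid, ridge])


def tracking_objective(unknowns: ForceUnknowns, dyn: TrunkDynamics,
                       state: SystemState, target_disp: np.ndarray, dt: float,
                       tracked: np.ndarray | None = None,
                       solver: SolverConfig | None = None) -> float:
    """Squared tracking discrepancy of one interval (m^2).

    Integrates the dynamics over ``[t, t+dt]`` with the candidate forces
    held constant and returns ``sum((dq_model - dq_target)^2)`` over the
    tracked DoFs.  ``target_disp`` is the observed displacement increment
    over the interval (full 3N vector; untracked entries ignored).
    Integration failures return a large penalty instead of raising, to keep
    an optimizer alive.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    solver = solver or _solver_of(dyn)
    if tracked is None:
        tracked = tracked_dof_indices(dyn.structure)
    r = _step_residuals(unknowns.to_vector(), dyn, state, target_disp, dt,
                        tracked, solver)
    return float(np.sum(r[: len(tracked)] ** 2))


def _solver_of(dyn: TrunkDynamics) -> SolverConfig:
    cfg = dyn.structure.config
    return cfg.solver if cfg is not None else SolverConfig()


def force_jacobian(dyn: TrunkDynamics, state: SystemState, dt: float,
                   tracked: np.ndarray, solver: SolverConfig | None = None,
                   fd_step: float = 10.0) -> np.ndarray:
    """Finite-difference Jacobian of the tracking residuals w.r.t. forces.

    The step response is nearly affine in the applied forces (the dynamics
    are linear except for the slowly varying rod directions), so one
    Jacobian evaluated at zero force is an excellent model of the whole
    step and can even be reused over a few consecutive steps while the
    geometry changes slowly.  Shape: (n_tracked + n_unknowns, n_unknowns),
    including the ridge rows appended by the residual function.
    """
    solver = solver or _solver_of(dyn)
    n_unk = 3 * dyn.structure.n_segments
    base = _step_residuals(np.zeros(n_unk), dyn, state,
                           np.zeros(dyn.structure.n_dof), dt, tracked, solver)
    J = np.zeros((len(base), n_unk))
    for j in range(n_unk):
        x = np.zeros(n_unk)
        x[j] = fd_step
        r = _step_residuals(x, dyn, state, np.zeros(dyn.structure.n_dof), dt,
                            tracked, solver)
        J[:, j] = (r - base) / fd_step
    return J


def estimate_step_forces(dyn: TrunkDynamics, state: SystemState,
                         target_disp: np.ndarray, dt: float,
                         warm_start: ForceUnknowns | None = None,
                         tracked: np.ndarray | None = None,
                         solver: SolverConfig | None = None,
                         jacobian: np.ndarray | None = None,
                         ) -> tuple[ForceUnknowns, dict]:
    """Bounded least-squares estimate of one interval's forces.

    The step response is affine in the forces to high accuracy (the only
    nonlinearity is the slow rotation of the rod axes), so when
    ``jacobian`` (from :func:`force_jacobian`) is given the problem is
    solved directly as a bounded linear least-squares system around the
    warm start -- one forward integration for the residual plus the shared
    Jacobian.  Without a Jacobian, a bounded nonlinear least-squares solve
    (scipy ``least_squares``, trust-region reflective, 2-point differences
    of ``solver.diff_step``) is used.  Returns the estimate and a
    diagnostics dict (objective, function evaluations, convergence flag);
    non-convergence returns the best iterate with ``converged=False``
    rather than raising.
    """
    solver = solver or _solver_of(dyn)
    n_seg = dyn.structure.n_segments
    if warm_start is None:
        warm_start = ForceUnknowns.zeros(n_seg)
    if tracked is None:
        tracked = tracked_dof_indices(dyn.structure)
    x0 = np.clip(warm_start.to_vector(), solver.force_bound_lower,
                 solver.force_bound)

    if jacobian is not None:
        r0 = _step_residuals(x0, dyn, state, target_disp, dt, tracked, solver)
        # r(x) ~ r0 + J (x - x0)  ->  min ||J x - (J x0 - r0)||, bounded
        res = lsq_linear(jacobian, jacobian @ x0 - r0,
                         bounds=(solver.force_bound_lower, solver.force_bound),
                         tol=solver.opt_tol, max_iter=solver.max_iterations)
        obj0 = float(np.sum(r0[: len(tracked)] ** 2))
        x, objective, nfev = x0, obj0, 1
        # backtracking toward the model optimum: the affine model degrades
        # for large force steps, so accept the largest fraction that helps
        for alpha in (1.0, 0.5, 0.25):
            xa = x0 + alpha * (res.x - x0)
            ra = _step_residuals(xa, dyn, state, target_disp, dt, tracked, solver)
            obja = float(np.sum(ra[: len(tracked)] ** 2))
            nfev += 1
            if obja < objective:
                x, objective = xa, obja
                break
        info = dict(objective=objective, iterations=nfev,
                    converged=bool(res.status >= 0))
        return ForceUnknowns.from_vector(x, n_seg), info

    res = least_squares(
        _step_residuals, x0,
        args=(dyn, state, target_disp, dt, tracked, solver),
        bounds=(solver.force_bound_lower, solver.force_bound),
        method="trf",
        x_scale=solver.force_scale,
        diff_step=solver.diff_step / np.maximum(1.0, np.abs(x0)),
        xtol=solver.opt_tol, ftol=solver.opt_tol, gtol=solver.opt_tol,
        max_nfev=solver.max_iterations * (3 * n_seg + 1),
    )
    est = ForceUnknowns.from_vector(res.x, n_seg)
    objective = float(np.sum(res.fun[: len(tracked)] ** 2))
    info = dict(objective=objective, iterations=int(res.nfev),
                converged=bool(res.status > 0))
    if not info["converged"]:
        warnings.warn("force estimation did not converge; returning best iterate")
    return est, info


def static_hold_forces(dyn: TrunkDynamics, q_target: np.ndarray,
                       solver: SolverConfig | None = None) -> ForceUnknowns:
    """Bounded linear least-squares static gravity balance at a configuration.

    Solves for the per-segment unknowns that minimize the residual nodal
    force (gravity minus passive tensions minus active resultants) over the
    free DoFs with the structure frozen at ``q_target``.  Used to warm-start
    sequential estimation and to initialize simulations at equilibrium.
    """
    solver = solver or _solver_of(dyn)
    structure = dyn.structure
    free = structure.free_dof_mask()
    n_unk = 3 * structure.n_segments
    base = dyn.internal_forces(q_target, None)
    r0 = (dyn.F_ext - base)[free]
    A = np.zeros((free.sum(), n_unk))
    for k in range(n_unk):
        x = np.zeros(n_unk)
        x[k] = 1.0
        fa = map_unknowns_to_rod_forces(
            structure, ForceUnknowns.from_vector(x, structure.n_segments))
        A[:, k] = -(dyn.internal_forces(q_target, fa) - base)[free]
    res = lsq_linear(A, -r0, bounds=(solver.force_bound_lower, solver.force_bound))
    return ForceUnknowns.from_vector(res.x, structure.n_segments)


def relax_center_nodes(dyn: TrunkDynamics, positions: np.ndarray,
                       fr: np.ndarray | None = None,
                       fr_split: str | None = None) -> np.ndarray:
    """Replace idealized section centers by their static sag positions.

    Idealized (mocap-style) targets put each center exactly on the
    backbone, but the model's center nodes hang on the four radial rods
    and must sag until the rod tensions balance their weight; pinning the
    targets to the unsagged centers leaves ~m*g of unbalanced force per
    section, which the very compliant trunk converts into decimeter-scale
    bending drift.  For each free section this solves the 3-DoF static
    balance of the center node -- gravity, passive radial-rod tensions to
    the (fixed) ring nodes, and the active radial forces ``fr`` of the
    section -- and returns a copy of ``positions`` with centers moved to
    equilibrium.
    """
    structure = dyn.structure
    pos = np.asarray(positions, float).copy()
    g = dyn.gravity
    if fr_split is None:
        fr_split = structure.config.fr_split if structure.config else "four-way"
    for sec in range(1, structure.n_sections + 1):
        cid = structure.node_id(sec, "O")
        if cid in structure.fixed_nodes:
            continue
        ring, ks, L0s, fas = [], [], [], []
        for role in ("P", "B", "Q", "A"):
            rod = structure.rods[structure.rod_id("radial", sec, role)]
            ring.append(pos[structure.node_id(sec, role)])
            ks.append(rod.axial_stiffness)
            L0s.append(rod.rest_length)
            fa = 0.0
            if fr is not None and sec >= 2:
                amount = fr[sec - 2]
                if fr_split == "four-way":
                    fa = amount / 4.0
                elif role in ("P", "Q"):
                    fa = amount / 2.0
            fas.append(fa)
        ring = np.array(ring)
        ks = np.array(ks)
        L0s = np.array(L0s)
        fas = np.array(fas)
        m = structure.nodes[cid].mass

        # start below the ring plane: the unsagged point is a stationary
        # flat spot of the vertical balance (dFz/dz ~ sag^2) where gradient
        # based solvers stall; the cube-root sag of the symmetric case is
        # an excellent seed
        r_ring = float(np.mean(np.linalg.norm(ring - pos[cid], axis=1)))
        sag = (m * g * r_ring**2 / (2.0 * ks.sum() + 1e-12)) ** (1.0 / 3.0)
        c = pos[cid] - np.array([0.0, 0.0, sag])

        # damped Newton on the 3-DoF balance with the analytic stiffness
        # of the four radial springs
        for _ in range(60):
            d = ring - c[None, :]
            L = np.linalg.norm(d, axis=1)
            u = d / L[:, None]
            tension = ks * (L - L0s) + fas
            f = (tension[:, None] * u).sum(axis=0)
            f[2] -= m * g
            if np.abs(f).max() < 1e-9:
                break
            Jc = np.zeros((3, 3))
            for un, Lv, Tv, kv in zip(u, L, tension, ks):
                P = np.outer(un, un)
                Jc += kv * P + (Tv / Lv) * (np.eye(3) - P)
            try:
                step = np.linalg.solve(Jc + 1e-9 * np.eye(3), f)
            except np.linalg.LinAlgError:
                break
            nstep = np.linalg.norm(step)
            if nstep > 0.5 * r_ring:  # trust region: keep inside the ring
                step *= 0.5 * r_ring / nstep
            c = c + step
        pos[cid] = c
    return pos


def static_shape_forces(dyn: TrunkDynamics, positions: np.ndarray,
                        solver: SolverConfig | None = None,
                        n_iter: int = 4) -> tuple[np.ndarray, ForceUnknowns]:
    """Self-consistent static forces holding a target outer-node shape.

    The center nodes are eliminated: for any candidate force set the
    centers are placed at their static sag (:func:`relax_center_nodes`,
    which depends on the radial forces), and the remaining ring/outer-node
    force balance is solved by bounded Gauss-Newton over the per-segment
    unknowns with a finite-difference Jacobian that therefore *includes*
    the center re-equilibration.  Solving the full structure instead, with
    centers pinned at the idealized backbone, leaves ~m*g per section
    unbalanced, which this very compliant structure converts into
    decimeter-scale drift.  Returns the relaxed absolute node positions
    and the force unknowns.
    """
    structure = dyn.structure
    solver = solver or _solver_of(dyn)
    rest = structure.rest_positions()
    free = structure.free_dof_mask()
    n_unk = 3 * structure.n_segments
    ring_free = free.copy()
    for nd in structure.nodes:
        if nd.role == "O":
            ring_free[3 * nd.node_id : 3 * nd.node_id + 3] = False

    def ring_residual(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        unk = ForceUnknowns.from_vector(x, structure.n_segments)
        pos = relax_center_nodes(dyn, positions, unk.fr)
        q = (pos - rest).ravel()
        q[~free] = 0.0
        fa = map_unknowns_to_rod_forces(structure, unk)
        r = (dyn.F_ext - dyn.internal_forces(q, fa))[ring_free]
        return r, pos

    x = np.zeros(n_unk)
    pos = np.asarray(positions, float)
    for _ in range(n_iter):
        r0, pos = ring_residual(x)
        if np.abs(r0).max() < 1e-6:
            break
        h = 1.0  # N
        A = np.zeros((len(r0), n_unk))
        for k in range(n_unk):
            xk = x.copy()
            xk[k] += h
            A[:, k] = (ring_residual(xk)[0] - r0) / h
        res = lsq_linear(A, -(r0 - A @ x),
                         bounds=(solver.force_bound_lower, solver.force_bound))
        x = res.x
    r0, pos = ring_residual(x)
    return pos, ForceUnknowns.from_vector(x, structure.n_segments)


def settle_to_equilibrium(dyn: TrunkDynamics, q0: np.ndarray,
                          forces: np.ndarray | None = None,
                          duration: float = 2.0) -> SystemState:
    """Integrate with constant forces until transients have decayed."""
    state = SystemState(q0.copy(), np.zeros_like(q0), 0.0)
    traj = dyn.integrate(state, forces, (0.0, duration),
                         t_eval=np.array([duration]))
    out = traj.states[-1]
    out.time = 0.0
    return out


def trial_node_targets(trial: MovementTrial, structure: TrunkStructure) -> np.ndarray:
    """Map a trial's ellipse rows onto model node positions.

    Each section contributes its center node and the four outer nodes at
    the semi-axis tips, in model node order.  Returns (n_times, n_nodes, 3).
    """
    if trial.n_rows != structure.n_sections:
        raise ValueError(
            f"trial has {trial.n_rows} rows but structure has "
            f"{structure.n_sections} sections")
    out = np.zeros((trial.n_times, structure.n_nodes, 3))
    for t, sample in enumerate(trial.sections):
        for sec in sample:
            base = 5 * (sec.row_index - 1)
            out[t, base : base + 5] = section_node_positions_from_ellipse(
                sec.center, sec.rotation, sec.semi_axes)
    return out


def run_inverse(targets: MovementTrial | np.ndarray, structure: TrunkStructure,
                dt: float | None = None, tracked_mode: str = "centers",
                planar: bool = True, dyn: TrunkDynamics | None = None,
                solver: SolverConfig | None = None, jac_refresh: int = 5,
                target_mode: str = "blended", feedback_gain: float = 0.2,
                feedback_clip: float = 0.01, static_init: bool = False,
                warm_mode: str = "previous",
                ) -> tuple[ActiveForceHistory, "np.ndarray"]:
    """Sequential per-step force estimation over a whole trial.

    ``targets`` is either a :class:`MovementTrial` (converted to node
    positions via the ellipse geometry) or a raw (n_times, n_nodes, 3)
    node-position array.  The initial model state is matched to the first
    sample.  The force Jacobian of the step response is recomputed every
    ``jac_refresh`` steps (the response is nearly affine in the forces, so
    a slightly stale Jacobian only slows convergence, never biases the
    minimum).

    ``target_mode`` selects how the per-step displacement target is formed.
    ``'increment'`` compares the raw per-interval displacement increments
    of data and model (open loop: deviations of untracked DoFs compound);
    ``'absolute'`` demands the full accumulated deviation be closed within
    one interval (a deadbeat demand that destabilizes a lightly damped
    structure); ``'blended'`` (default) tracks the increment plus
    ``feedback_gain`` times the accumulated deviation, clipped entrywise at
    ``feedback_clip`` meters per step -- a gentle servo that corrects
    drift over ~1/gain steps without exciting ringing.

    ``warm_mode='previous'`` warm-starts each step from the previous
    estimate; ``'static'`` warm-starts from the static gravity balance at
    the next target sample, anchoring the estimates to the quasi-static
    force-shape relation for slow movements.

    Returns the estimated history (``n_times - 1`` entries) and the
    simulated node trajectory produced by applying the estimated forces
    sequentially, shape (n_times, n_nodes, 3).
    """
    if target_mode not in ("absolute", "increment", "blended"):
        raise ValueError(f"unknown target_mode {target_mode!r}")
    if isinstance(targets, MovementTrial):
        if dt is None:
            dt = 1.0 / targets.sample_rate
        targets = trial_node_targets(targets, structure)
    targets = np.asarray(targets, float)
    if dt is None:
        raise ValueError("dt is required when targets are raw positions")
    if targets.shape[1] != structure.n_nodes:
        raise ValueError("target node count does not match the structure")

    dyn = dyn or TrunkDynamics(structure)
    solver = solver or _solver_of(dyn)
    tracked = tracked_dof_indices(structure, tracked_mode, planar)
    rest = structure.rest_positions()
    n_steps = targets.shape[0] - 1
    n_seg = structure.n_segments

    q0 = (targets[0] - rest).ravel()
    q0[~structure.free_dof_mask()] = 0.0
    state = SystemState(q0, np.zeros_like(q0), 0.0)
    warm0 = ForceUnknowns.zeros(n_seg)
    if static_init:
        # start at the gravity-loaded equilibrium nearest the first sample,
        # holding it with statically balanced forces: idealized (rigid-
        # section, unsagged) targets would otherwise inject a long-ringing
        # pendular transient of the weakly damped backbone centers
        warm0 = static_hold_forces(dyn, q0, solver)
        fvec = map_unknowns_to_rod_forces(structure, warm0)
        state = settle_to_equilibrium(dyn, q0, fvec)

    hist = ActiveForceHistory(
        times=np.arange(n_steps) * dt,
        fl_dorsal=np.zeros((n_steps, n_seg)),
        fl_ventral=np.zeros((n_steps, n_seg)),
        fr=np.zeros((n_steps, n_seg)),
    )
    sim = np.zeros_like(targets)
    sim[0] = rest + state.q.reshape(-1, 3)
    warm = warm0
    jac = None
    for j in range(n_steps):
        if j % max(jac_refresh, 1) == 0:
            jac = force_jacobian(dyn, state, dt, tracked, solver)
        if target_mode == "absolute":
            target_disp = (targets[j + 1] - rest).ravel() - state.q
        elif target_mode == "blended":
            inc = (targets[j + 1] - targets[j]).ravel()
            err = (targets[j] - rest).ravel() - state.q
            corr = np.clip(feedback_gain * err, -feedback_clip, feedback_clip)
            target_disp = inc + corr
        else:
            target_disp = (targets[j + 1] - targets[j]).ravel()
        if warm_mode == "static":
            qn = (targets[j + 1] - rest).ravel()
            qn[~structure.free_dof_mask()] = 0.0
            warm = static_hold_forces(dyn, qn, solver)
        est, info = estimate_step_forces(dyn, state, target_disp, dt,
                                         warm_start=warm, tracked=tracked,
                                         solver=solver, jacobian=jac)
        hist.fl_dorsal[j] = est.fl_dorsal
        hist.fl_ventral[j] = est.fl_ventral
        hist.fr[j] = est.fr
        hist.residual[j] = info["objective"]
        hist.iterations[j] = info["iterations"]
        hist.converged[j] = info["converged"]
        forces = map_unknowns_to_rod_forces(structure, est)
        state = dyn.step(state, forces, dt, rtol=solver.rtol, atol=solver.atol)
        sim[j + 1] = rest + state.q.reshape(-1, 3)
        warm = est
    return hist, sim
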