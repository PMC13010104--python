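"""Forward dynamics of the assembled trunk network.

The equation of motion of the full structure is

    M qdd + F_el(q) + C qd + F_act(q) = F_ext

with ``q`` the 3N vector of node displacements from rest, ``M`` the lumped
(diagonal) mass matrix, ``F_el`` the nodal resultants of the passive rod
tensions and ``F_act`` those of the active axial rod forces; ``F_ext`` is
the gravity load.  Both force families act along the *current* (deformed)
rod axes: a rod of stiffness ``k = E*A/L0`` carries the passive tension
``k * (|d| - L0)`` where ``d`` is the current endpoint separation.  This is
the exact axial-rod elasticity, whose linearization at rest is the
assembled stiffness matrix ``K_glob`` of :func:`~trunksim.trunk_model.
assemble_global`; the geometric form is required because the backbone
center nodes, held only by in-plane radial rods, have no first-order axial
stiffness and would otherwise be an unsupported mechanism under gravity.
``C = c*M`` is an optional mass-proportional viscous damping term (the
physical trunk dissipates internally; an undamped stiff network driven by
piecewise-constant forces rings unphysically -- set ``c = 0`` to disable).
Displacements of fixed (base) nodes are clamped to zero.

Integration uses an adaptive Runge-Kutta (Dormand-Prince 4/5) scheme;
piecewise-constant force schedules are integrated interval by interval so
force discontinuities always fall on step boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .trunk_model import TrunkStructure

__all__ = [
    "SystemState",
    "TrunkDynamics",
    "IntegrationError",
    "gravity_load",
    "nodal_active_resultants",
]

G_DEFAULT = 9.81  # m/s^2


class IntegrationError(RuntimeError):
    pass


@dataclass
class SystemState:
    """Displacements and velocities of all nodes at one time."""

    q: np.ndarray  # (3N,) m
    qdot: np.ndarray  # (3N,) m/s
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.q.copy(), self.qdot.copy(), self.time)


def gravity_load(structure: TrunkStructure, g: float = G_DEFAULT) -> np.ndarray:
    """External load vector: -m*g on every node's Z DoF.

    Entries of fixed nodes are retained (useful for reaction reporting) but
    are not applied during integration, where fixed DoFs stay clamped.
    """
    F = np.zeros(structure.n_dof)
    F[2::3] = -structure.masses() * g
    return F


def nodal_active_resultants(structure: TrunkStructure, forces: np.ndarray,
                            positions: np.ndarray) -> np.ndarray:
    """Nodal resultants of the active axial rod forces.

    ``forces[r] > 0`` means rod ``r`` contracts: it pulls its two endpoints
    toward each other along the current rod axis.  Every rod contributes
    equal and opposite forces to its endpoints, so the resultants sum to
    zero globally.  Returned with the sign convention of the equation of
    motion (``... + F_act = F_ext``): the entry is the force that must be
    *added* on the left-hand side.
    """
    forces = np.asarray(forces, dtype=float)
    out = np.zeros((structure.n_nodes, 3))
    pos = np.asarray(positions, dtype=float).reshape(structure.n_nodes, 3)
    active = np.nonzero(forces)[0]
    for r in active:
        rod = structure.rods[r]
        i, j = rod.endpoints
        d = pos[j] - pos[i]
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise IntegrationError(f"rod {rod.rod_id} has zero length; cannot orient force")
        u = d / n
        # contraction pulls i toward j and j toward i
        out[i] -= forces[r] * u
        out[j] += forces[r] * u
    return out.ravel()


class TrunkDynamics:
    """Precomputed matrices + right-hand side for one structure.

    Parameters
    ----------
    structure:
        The assembled trunk (or any point-mass truss).
    damping:
        Mass-proportional viscous coefficient c (1/s); C = c*M.
    gravity:
        Gravitational acceleration (m/s^2) along -Z; 0 disables gravity.
    """

    def __init__(self, structure: TrunkStructure, damping: float | None = None,
                 gravity: float | None = None, axial_damping: float | None = None):
        cfg = structure.config
        self.structure = structure
        self.damping = damping if damping is not None else (cfg.damping if cfg else 2.0)
        self.axial_damping = axial_damping if axial_damping is not None else (
            cfg.axial_damping if cfg else 0.0)
        self.gravity = gravity if gravity is not None else (cfg.gravity if cfg else G_DEFAULT)
        self.m_diag = np.repeat(structure.masses(), 3)
        if np.any(self.m_diag <= 0):
            raise IntegrationError("singular mass matrix: non-positive node mass")
        self.free = structure.free_dof_mask()
        self.rest = structure.rest_positions()
        self.F_ext = gravity_load(structure, self.gravity)
        # vectorized rod tables
        self._ei = np.array([r.endpoints[0] for r in structure.rods])
        self._ej = np.array([r.endpoints[1] for r in structure.rods])
        self._k = np.array([r.axial_stiffness for r in structure.rods])
        self._L0 = np.array([r.rest_length for r in structure.rods])
        # signed incidence (n_nodes, n_rods): row scatter of rod pulls
        inc = np.zeros((structure.n_nodes, structure.n_rods))
        inc[self._ei, np.arange(structure.n_rods)] = -1.0
        inc[self._ej, np.arange(structure.n_rods)] = 1.0
        self._incidence = inc

    def rest_state(self) -> SystemState:
        n = self.structure.n_dof
        return SystemState(np.zeros(n), np.zeros(n), 0.0)

    def internal_forces(self, q: np.ndarray, active: np.ndarray | None = None,
                        qdot: np.ndarray | None = None) -> np.ndarray:
        """Nodal resultants of passive tensions plus active forces (3N,).

        Passive rods are Kelvin-Voigt elements: tension
        ``k*(|d| - L0) + axial_damping*k*d|d|/dt`` along the current axis.
        Sign follows the left-hand side of the equation of motion: positive
        entries oppose the motion they would produce.
        """
        pos = self.rest + q.reshape(-1, 3)
        d = pos[self._ej] - pos[self._ei]
        lengths = np.linalg.norm(d, axis=1)
        if np.any(lengths < 1e-12):
            raise IntegrationError("a rod collapsed to zero length")
        u = d / lengths[:, None]
        tension = self._k * (lengths - self._L0)
        if qdot is not None and self.axial_damping > 0.0:
            v = qdot.reshape(-1, 3)
            stretch_rate = np.sum((v[self._ej] - v[self._ei]) * u, axis=1)
            tension = tension + self.axial_damping * self._k * stretch_rate
        if active is not None:
            tension = tension + np.asarray(active, float)
        # physical pull on node i is +tension*u (toward j); the left-hand-side
        # term of the equation of motion is its negative
        out = self._incidence @ (tension[:, None] * u)
        return out.ravel()

    def elastic_energy(self, q: np.ndarray) -> float:
        """Passive strain energy sum(1/2 k (|d|-L0)^2), J."""
        pos = self.rest + q.reshape(-1, 3)
        stretch = np.linalg.norm(pos[self._ej] - pos[self._ei], axis=1) - self._L0
        return float(0.5 * np.sum(self._k * stretch**2))

    def equations_of_motion(self, state: SystemState, forces: np.ndarray) -> np.ndarray:
        """Acceleration vector qdd for the current state and active forces."""
        return self._acceleration(state.q, state.qdot, np.asarray(forces, float))

    def _acceleration(self, q: np.ndarray, qdot: np.ndarray, forces: np.ndarray) -> np.ndarray:
        rhs = self.F_ext - self.internal_forces(q, forces, qdot) \
            - self.damping * self.m_diag * qdot
        acc = rhs / self.m_diag
        acc[~self.free] = 0.0
        return acc

    # -- integration -------------------------------------------------------
    def integrate(self, state0: SystemState,
                  force_schedule: Callable[[float], np.ndarray] | np.ndarray | None,
                  t_span: tuple[float, float], t_eval: np.ndarray | None = None,
                  rtol: float = 1e-7, atol: float = 1e-10) -> "Trajectory":
        """Integrate the equation of motion over ``t_span``.

        ``force_schedule`` maps time to a per-rod active force vector (or is
        a constant vector / None for passive dynamics).  Fixed DoFs are
        clamped to zero throughout.  Raises :class:`IntegrationError` on
        solver failure or non-finite state.
        """
        n = self.structure.n_dof
        if force_schedule is None:
            force_schedule = np.zeros(self.structure.n_rods)
        if isinstance(force_schedule, np.ndarray):
            const = force_schedule

            def schedule(_t: float) -> np.ndarray:
                return const
        else:
            schedule = force_schedule

        q0 = state0.q.copy()
        qd0 = state0.qdot.copy()
        q0[~self.free] = 0.0
        qd0[~self.free] = 0.0

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            q, qd = y[:n], y[n:]
            acc = self._acceleration(q, qd, schedule(t))
            dq = qd.copy()
            dq[~self.free] = 0.0
            return np.concatenate([dq, acc])

        sol = solve_ivp(rhs, t_span, np.concatenate([q0, qd0]), method="RK45",
                        t_eval=t_eval, rtol=rtol, atol=atol, dense_output=False)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"integration failed near t={sol.t[-1] if len(sol.t) else t_span[0]}: "
                f"{sol.message}"
            )
        states = [SystemState(sol.y[:n, i].copy(), sol.y[n:, i].copy(), float(sol.t[i]))
                  for i in range(sol.y.shape[1])]
        return Trajectory(states=states, structure=self.structure)

    def step(self, state: SystemState, forces: np.ndarray, dt: float,
             rtol: float = 1e-7, atol: float = 1e-10) -> SystemState:
        """Advance one interval with the active forces held constant."""
        traj = self.integrate(state, np.asarray(forces, float),
                              (state.time, state.time + dt), rtol=rtol, atol=atol)
        return traj.states[-1]

    def simulate_schedule(self, state0: SystemState, force_sequence: np.ndarray,
                          dt: float, rtol: float = 1e-7, atol: float = 1e-10) -> "Trajectory":
        """Integrate a piecewise-constant force schedule.

        ``force_sequence`` has shape (n_steps, n_rods); interval ``j`` spans
        ``[t0 + j*dt, t0 + (j+1)*dt)``.  The returned trajectory is sampled
        at the interval boundaries (n_steps + 1 states).
        """
        states = [state0.copy()]
        s = state0
        for f in np.asarray(force_sequence, float):
            s = self.step(s, f, dt, rtol=rtol, atol=atol)
            states.append(s)
        return Trajectory(states=states, structure=self.structure)


@dataclass
class Trajectory:
    """A sampled solution of the equation of motion."""

    states: list[SystemState]
    structure: TrunkStructure
    times: np.ndarray = field(init=False)

    def __post_init__(self):
        self.times = np.array([s.time for s in self.states])

    def positions(self) -> np.ndarray:
        """Node positions, shape (n_times, n_nodes, 3)."""
        rest = self.structure.rest_positions()
        return np.array([rest + s.q.reshape(-1, 3) for s in self.states])

    def displacements(self) -> np.ndarray:
        return np.array([s.q for s in self.states])
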