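"""Seeded generator of planar reaching trials and ground-truth forces.

The generator emulates the structure of motion-capture trunk recordings:
ten elliptical cross-section rows sampled at ~100 Hz, segment rest lengths
of ~0.2 m, planar bending up to tens of deg/m and elongations up to ~20% of
segment length, with optional Gaussian noise on the ellipse centers.

Commanded per-segment curvature and length follow a minimum-jerk time
profile (smooth start and stop, the standard kinematic model of reaching).
Section frames are reconstructed by composing the per-segment bend
rotations along the backbone; for bending+elongation (BE) trials the
cross-section radii scale as ``sqrt(L_rest / L(t))`` so the elliptic-
frustum volume of every segment is preserved analytically, the defining
constraint of a muscular hydrostat.

All randomness flows through the explicit seed; the same seed yields a
bit-identical trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .config import RunConfig
from .dynamics import IntegrationError, TrunkDynamics
from .force_estimation import ActiveForceHistory, ForceUnknowns, map_unknowns_to_rod_forces
from .kinematics import EllipseSection, MovementTrial, ShapeSeries
from .trunk_model import TrunkStructure

__all__ = [
    "GeneratorSpec",
    "generate_reaching_trial",
    "generate_ground_truth_forces",
    "generate_marker_rows",
]


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic planar reaching trial."""

    movement_class: str = "B"  # "B" or "BE"
    peak_K: float = 40.0  # deg/m, commanded curvature at the movement peak
    elongation_fraction: float = 0.0  # of segment rest length, 0..0.3
    duration: float = 2.0  # s
    sample_rate: float = 100.0  # Hz
    noise_sd: float = 0.0  # m, Gaussian noise on ellipse centers
    seed: int = 0
    n_sections: int = 10
    segment_weights: np.ndarray | None = None  # per-segment K scaling

    def __post_init__(self):
        if self.movement_class not in ("B", "BE"):
            raise ValueError("movement_class must be 'B' or 'BE'")
        if self.peak_K < 0 or self.noise_sd < 0:
            raise ValueError("peak_K and noise_sd must be non-negative")
        if not 0.0 <= self.elongation_fraction <= 0.3:
            raise ValueError("elongation_fraction must lie in [0, 0.3]")
        if self.movement_class == "B" and self.elongation_fraction > 0.0:
            raise ValueError("pure bending trials cannot command elongation")


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


def _base_frame() -> np.ndarray:
    """Rest frame of the first section: dorsal +X, lateral +Y.

    The frame normal (third column) is dorsal x lateral = +Z; the hanging
    backbone advances along the *negative* normal, so at rest the frame is
    the identity and outer nodes match the structure's rest layout.
    """
    return np.eye(3)


def generate_reaching_trial(spec: GeneratorSpec,
                            config: RunConfig | None = None,
                            ) -> tuple[MovementTrial, ShapeSeries]:
    """Generate a planar reaching trial and its ground-truth shape series.

    The geometry (segment rest length, section radii) is taken from
    ``config`` so generated trials are compatible with the structure built
    from the same configuration.  Returns the trial (ellipse rows over
    time) and the commanded per-segment (K, L) series, which serves as the
    oracle for the kinematics pipeline.
    """
    config = config or RunConfig(n_sections=spec.n_sections)
    if config.n_sections != spec.n_sections:
        config = config.model_copy(update={"n_sections": spec.n_sections})
    rng = np.random.default_rng(spec.seed)
    ns = spec.n_sections
    n_seg = ns - 1
    L_rest = config.segment_rest_length
    radii = np.linspace(config.base_radius, config.tip_radius, ns)

    n_t = int(np.floor(spec.duration * spec.sample_rate)) + 1
    times = np.arange(n_t) / spec.sample_rate
    s = minimum_jerk(times / spec.duration)

    w = np.ones(n_seg) if spec.segment_weights is None else np.asarray(spec.segment_weights, float)
    if len(w) != n_seg:
        raise ValueError("segment_weights length must equal n_segments")
    K_cmd = spec.peak_K * np.outer(w, s)  # (n_seg, n_t), deg/m
    elong = spec.elongation_fraction if spec.movement_class == "BE" else 0.0
    L_cmd = L_rest * (1.0 + elong * np.ones((n_seg, 1)) * s[None, :])

    # hydrostat constraint: radius scale sqrt(L_rest / L) preserves the
    # elliptic-frustum volume of every segment exactly
    scale = np.sqrt(L_rest / L_cmd[0])  # uniform elongation -> one scale

    samples: list[list[EllipseSection]] = []
    noise = rng.normal(0.0, spec.noise_sd, size=(n_t, ns, 3)) if spec.noise_sd > 0 else None
    for t in range(n_t):
        R = _base_frame()
        c = np.zeros(3)
        rows = [
            _section(1, c, R, radii[0] * scale[t], times[t], noise, t)
        ]
        for i in range(n_seg):
            theta = np.radians(K_cmd[i, t] * L_cmd[i, t])  # bend angle, rad
            half = Rotation.from_rotvec([0.0, theta / 2.0, 0.0]).as_matrix()
            full = Rotation.from_rotvec([0.0, theta, 0.0]).as_matrix()
            chord_dir = -(R @ half)[:, 2]  # tangent rotated by half the bend
            c = c + L_cmd[i, t] * chord_dir
            R = R @ full
            rows.append(_section(i + 2, c, R, radii[i + 1] * scale[t],
                                 times[t], noise, t))
        samples.append(rows)

    trial = MovementTrial(sections=samples, sample_rate=spec.sample_rate,
                          label=spec.movement_class, n_rows=ns)
    truth = ShapeSeries(times=times, K=K_cmd, K_alpha=K_cmd,
                        K_beta=np.zeros_like(K_cmd),
                        alpha=K_cmd * L_cmd, beta=np.zeros_like(K_cmd),
                        L=L_cmd)
    return trial, truth


def _section(row: int, center: np.ndarray, R: np.ndarray, radius: float,
             t: float, noise: np.ndarray | None, ti: int) -> EllipseSection:
    c = center.copy()
    if noise is not None:
        c = c + noise[ti, row - 1]
    return EllipseSection.from_rotation(row, c, R, (radius, radius), timestamp=t)


def generate_ground_truth_forces(structure: TrunkStructure, seed: int = 0,
                                 n_steps: int = 50, dt: float = 0.02,
                                 amplitude: float = 30.0,
                                 dyn: TrunkDynamics | None = None,
                                 max_redraws: int = 5):
    """Draw a smooth random force history and forward-integrate it.

    The per-segment unknowns follow seeded smooth half-sine envelopes with
    a random second-harmonic modulation, non-negative throughout (active
    rod forces are contraction-only, as muscles pull).  Used as the
    parameter-recovery oracle for the inverse-dynamics estimator: the
    returned trajectory, fed back into
    :func:`~trunksim.force_estimation.run_inverse`, should reproduce the
    returned history.  Unstable draws (non-finite trajectories) are redrawn
    up to ``max_redraws`` times.

    Returns ``(positions, history)`` with positions of shape
    (n_steps + 1, n_nodes, 3).
    """
    dyn = dyn or TrunkDynamics(structure)
    n_seg = structure.n_segments
    t_mid = np.arange(n_steps) * dt  # force of interval j, applied on [t_j, t_j+1)
    T = n_steps * dt
    for attempt in range(max_redraws + 1):
        rng = np.random.default_rng((seed + 1000003 * attempt) % 2**31)
        amp = rng.uniform(0.2, 1.0, size=(3, n_seg, 1)) * amplitude
        mod = rng.uniform(-0.8, 0.8, size=(3, n_seg, 1))
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(3, n_seg, 1))
        series = (amp * np.sin(np.pi * t_mid / T)
                  * (1.0 + mod * np.sin(2.0 * np.pi * t_mid / T + phase)))
        hist = ActiveForceHistory(
            times=t_mid,
            fl_dorsal=series[0].T.copy(),
            fl_ventral=series[1].T.copy(),
            fr=series[2].T.copy(),
        )
        try:
            seq = np.array([
                map_unknowns_to_rod_forces(structure, hist.step(j))
                for j in range(n_steps)
            ])
            traj = dyn.simulate_schedule(dyn.rest_state(), seq, dt)
        except IntegrationError:
            continue
        pos = traj.positions()
        if np.all(np.isfinite(pos)):
            return pos, hist
    raise IntegrationError(
        f"no stable force draw found after {max_redraws + 1} attempts")


def generate_marker_rows(trial: MovementTrial, markers_per_row: int = 8,
                         arc_deg: float = 360.0, noise_sd: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Sample reflective-marker positions on each section ellipse.

    Markers are spread uniformly over an arc of ``arc_deg`` degrees centered
    on the dorsal direction (mocap markers sit on the dorsal side only), with
    optional Gaussian position noise.  Returns a tidy table with columns
    ``time, row_index, marker_id, x, y, z``.
    """
    rng = np.random.default_rng(seed)
    if arc_deg >= 360.0:
        phis = np.linspace(0.0, 2.0 * np.pi, markers_per_row, endpoint=False)
    else:
        half = np.radians(arc_deg) / 2.0
        phis = np.linspace(-half, half, markers_per_row)
    rows = []
    for t, sample in enumerate(trial.sections):
        for sec in sample:
            R = sec.rotation
            a, b = sec.semi_axes
            pts = (sec.center[None, :]
                   + np.outer(a * np.cos(phis), R[:, 0])
                   + np.outer(b * np.sin(phis), R[:, 1]))
            if noise_sd > 0:
                pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
            for m, p in enumerate(pts):
                rows.append(dict(time=trial.times[t], row_index=sec.row_index,
                                 marker_id=m, x=p[0], y=p[1], z=p[2]))
    return pd.DataFrame(rows)
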