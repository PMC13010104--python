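"""Trajectory error metrics and trunk volume computation.

Trajectory accuracy between a simulated and a reference node trajectory is
summarized per node by the mean absolute error (MAE) and root-mean-square
error (RMSE) of the planar (X, Z) Euclidean deviation, plus the relative
MAE: the node's MAE divided by the arc length of its reference path, in
percent.  Trunk volume treats each segment as a hexahedron spanned by the
four outer nodes of its two bounding sections, decomposed into six
tetrahedra with a fixed diagonal convention so volumes are bit
reproducible; an elliptic-frustum variant computes volume directly from
ellipse parameters.  Volume conservation is reported as the percentage
mean absolute deviation from a reference resting volume -- the muscular-
hydrostat constraint the model is expected to respect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import MovementTrial
from .trunk_model import TrunkStructure

__all__ = [
    "ErrorReport",
    "VolumeSeries",
    "trajectory_errors",
    "segment_volume",
    "volume_series",
    "trial_volume_series",
]


@dataclass
class ErrorReport:
    """Per-node trajectory error metrics (planar X-Z deviations)."""

    node_ids: np.ndarray
    mae: np.ndarray  # m
    rmse: np.ndarray  # m
    rel_mae: np.ndarray  # %, NaN where the reference path has zero length
    path_length: np.ndarray  # m, reference path arc length per node

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(node_id=self.node_ids, mae=self.mae,
                                 rmse=self.rmse, rel_mae=self.rel_mae,
                                 path_length=self.path_length))

    def node(self, node_id: int) -> dict:
        i = int(np.flatnonzero(self.node_ids == node_id)[0])
        return dict(mae=float(self.mae[i]), rmse=float(self.rmse[i]),
                    rel_mae=float(self.rel_mae[i]),
                    path_length=float(self.path_length[i]))


def trajectory_errors(sim: np.ndarray, ref: np.ndarray,
                      node_ids: np.ndarray | None = None) -> ErrorReport:
    """Per-node MAE / RMSE / relative MAE between two node trajectories.

    Both inputs have shape (n_times, n_nodes, 3); deviations are measured
    in the 2D X-Z plane (planar movements).  The relative MAE of a node is
    its MAE divided by the arc length of the *reference* path of that node,
    in percent; nodes with a zero-length reference path get NaN with a
    warning instead of a division error.
    """
    sim = np.asarray(sim, float)
    ref = np.asarray(ref, float)
    if sim.shape != ref.shape:
        raise ValueError(f"trajectory shapes differ: {sim.shape} vs {ref.shape}")
    dev = np.linalg.norm((sim - ref)[:, :, [0, 2]], axis=2)  # (T, N)
    mae = dev.mean(axis=0)
    rmse = np.sqrt((dev**2).mean(axis=0))
    seg = np.linalg.norm(np.diff(ref[:, :, [0, 2]], axis=0), axis=2)
    path = seg.sum(axis=0) if len(ref) > 1 else np.zeros(ref.shape[1])
    rel = np.full_like(mae, np.nan)
    moving = path > 0
    if not np.all(moving):
        warnings.warn("some reference node paths have zero length; their "
                      "relative MAE is undefined (NaN)")
    rel[moving] = 100.0 * mae[moving] / path[moving]
    ids = np.arange(sim.shape[1]) if node_ids is None else np.asarray(node_ids)
    return ErrorReport(node_ids=ids, mae=mae, rmse=rmse, rel_mae=rel,
                       path_length=path)


# 6-tetrahedron decomposition of a hexahedron (corners 0-3 = base i with
# consistent winding, 4-7 = base i+1 aligned above them), all sharing the
# 0-6 diagonal.  Fixed convention => bit-reproducible volumes.
_HEX_TETS = ((0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
             (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6))


def segment_volume(corners: np.ndarray) -> float:
    """Signed volume (m^3) of one hexahedral trunk segment.

    ``corners`` are 8 ordered 3-vectors: the four outer nodes of the
    proximal section then the four of the distal section, same winding.
    The hexahedron is decomposed into six tetrahedra sharing the 0-6
    diagonal; the result is positive for a consistently wound,
    non-degenerate ordering.  A fully coplanar corner set returns 0.0 with
    a warning.
    """
    c = np.asarray(corners, float)
    if c.shape != (8, 3):
        raise ValueError(f"expected 8 corners of 3 coordinates, got {c.shape}")
    vol = 0.0
    for i, j, k, l in _HEX_TETS:
        vol += np.linalg.det(np.array([c[j] - c[i], c[k] - c[i], c[l] - c[i]])) / 6.0
    span = np.linalg.matrix_rank(c - c.mean(axis=0), tol=1e-12)
    if span < 3:
        warnings.warn("degenerate (coplanar) segment corners; volume is 0")
        return 0.0
    return float(vol)


@dataclass
class VolumeSeries:
    """Total and per-segment trunk volumes over time."""

    times: np.ndarray
    total: np.ndarray  # (T,) m^3
    per_segment: np.ndarray  # (T, n_segments) m^3
    reference: float  # resting volume, m^3

    @property
    def mae_percent(self) -> float:
        """Mean absolute deviation from the reference volume, in %."""
        return float(np.mean(np.abs(self.total - self.reference))
                     / self.reference * 100.0)


def _structure_corners(structure: TrunkStructure, positions: np.ndarray,
                       segment: int) -> np.ndarray:
    # the trunk advances along -Z at rest while the section winding
    # (P,B,Q,A) is counterclockwise viewed from +Z, so the distal section
    # is the hexahedron's first face for a positive volume
    order = ("P", "B", "Q", "A")
    lo = [structure.node_id(segment + 1, r) for r in order]
    hi = [structure.node_id(segment, r) for r in order]
    return positions[lo + hi]


def volume_series(trajectory: np.ndarray, structure: TrunkStructure,
                  times: np.ndarray | None = None,
                  reference: float | None = None) -> VolumeSeries:
    """Hexahedral trunk volume over a node trajectory (T, n_nodes, 3).

    The reference defaults to the volume of the resting structure.
    """
    traj = np.asarray(trajectory, float)
    T = traj.shape[0]
    nseg = structure.n_segments
    per = np.zeros((T, nseg))
    for t in range(T):
        for s in range(1, nseg + 1):
            per[t, s - 1] = segment_volume(_structure_corners(structure, traj[t], s))
    if reference is None:
        rest = structure.rest_positions()
        reference = float(sum(
            segment_volume(_structure_corners(structure, rest, s))
            for s in range(1, nseg + 1)))
    times = np.arange(T, dtype=float) if times is None else np.asarray(times, float)
    return VolumeSeries(times=times, total=per.sum(axis=1), per_segment=per,
                        reference=reference)


def elliptic_frustum_volume(a1: float, b1: float, a2: float, b2: float,
                            h: float) -> float:
    """Volume of a frustum with elliptic bases (prismatoid closed form)."""
    s1, s2 = np.pi * a1 * b1, np.pi * a2 * b2
    return h / 3.0 * (s1 + s2 + np.sqrt(s1 * s2))


def trial_volume_series(trial: MovementTrial,
                        reference: float | None = None) -> VolumeSeries:
    """Elliptic-frustum trunk volume of a recorded/generated trial.

    Each segment is a frustum between consecutive section ellipses; the
    reference defaults to the first sample's volume (resting configuration).
    """
    T = trial.n_times
    nseg = trial.n_rows - 1
    per = np.zeros((T, nseg))
    for t, sample in enumerate(trial.sections):
        for i in range(nseg):
            s1, s2 = sample[i], sample[i + 1]
            h = float(np.linalg.norm(s2.center - s1.center))
            per[t, i] = elliptic_frustum_volume(*s1.semi_axes, *s2.semi_axes, h)
    if reference is None:
        reference = float(per[0].sum())
    return VolumeSeries(times=trial.times.copy(), total=per.sum(axis=1),
                        per_segment=per, reference=reference)
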