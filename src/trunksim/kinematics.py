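"""Trunk kinematics: ellipse cross-sections to segment shape descriptors.

Motion capture yields, per time sample, ten elliptical cross-sections of the
trunk (fitted to dorsal marker rows).  Each ellipse is described by eight
parameters: 3D center, ZYX-intrinsic Euler angles of its frame, and the two
semi-axis lengths.  From consecutive ellipses we derive per-segment shape
descriptors:

* segment length ``L`` -- Euclidean distance between consecutive centers;
* bend angles ``alpha``/``beta`` -- components of the relative rotation
  between consecutive section frames about the two in-plane section axes
  (the torsional component about the section normal is discarded: planar
  movements only);
* curvature components ``K_alpha = alpha/L``, ``K_beta = beta/L`` and the
  curvature magnitude ``K = sqrt(K_alpha^2 + K_beta^2)``, reported in deg/m
  to match the classification thresholds.

Movements are classified as pure bending (B) when curvature crosses a
threshold somewhere along the trunk while segment lengths stay near rest,
and bending+elongation (BE) when a length change threshold is also crossed.

Angles are stored internally in radians and reported in degrees; curvature
is always reported in deg/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EllipseSection",
    "SegmentShape",
    "ShapeSeries",
    "MovementTrial",
    "ClassThresholds",
    "MovementClass",
    "KinematicsError",
    "fit_section_ellipse",
    "segment_length",
    "relative_bend_angles",
    "segment_curvature",
    "shape_timeseries",
    "classify_movement",
]


class KinematicsError(ValueError):
    """Invalid kinematic input."""


@dataclass(frozen=True)
class EllipseSection:
    """One trunk cross-section ellipse at one time instant.

    The section frame has columns (u, v, n): u along the semi-major axis
    (dorsal direction in the model convention), v along the semi-minor axis,
    n the plane normal (local backbone tangent).  ``euler_zyx`` are the
    intrinsic Z-Y-X Euler angles of that frame.
    """

    row_index: int
    center: np.ndarray  # (3,) m
    euler_zyx: np.ndarray  # (3,) rad
    semi_axes: tuple[float, float]  # (a, b) m, a >= b
    timestamp: float = 0.0
    fit_rms: float | None = None  # residual of the ellipse fit, m

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "euler_zyx", np.asarray(self.euler_zyx, dtype=float))
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise KinematicsError(f"row {self.row_index}: semi-axes must be positive")
        if not np.all(np.isfinite(self.euler_zyx)):
            raise KinematicsError(f"row {self.row_index}: non-finite Euler angles")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 orientation matrix, columns (major, minor, normal)."""
        return Rotation.from_euler("ZYX", self.euler_zyx).as_matrix()

    @classmethod
    def from_rotation(cls, row_index: int, center: np.ndarray, R: np.ndarray,
                      semi_axes: tuple[float, float], timestamp: float = 0.0,
                      fit_rms: float | None = None) -> "EllipseSection":
        eul = Rotation.from_matrix(R).as_euler("ZYX")
        return cls(row_index, np.asarray(center, float), eul,
                   (float(semi_axes[0]), float(semi_axes[1])), timestamp, fit_rms)


@dataclass(frozen=True)
class SegmentShape:
    """Per-segment curvature and length at one time instant (deg/m, m)."""

    segment_index: int
    K: float
    K_alpha: float
    K_beta: float
    alpha: float  # deg
    beta: float  # deg
    L: float  # m


@dataclass
class ShapeSeries:
    """Time series of segment shapes, stored as (n_segments, n_times) arrays."""

    times: np.ndarray
    K: np.ndarray
    K_alpha: np.ndarray
    K_beta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    L: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.K.shape[0]

    @property
    def n_times(self) -> int:
        return self.K.shape[1]

    def segment(self, segment_index: int) -> list[SegmentShape]:
        """SegmentShape objects for one 1-based segment index."""
        i = segment_index - 1
        return [
            SegmentShape(segment_index, self.K[i, t], self.K_alpha[i, t],
                         self.K_beta[i, t], self.alpha[i, t], self.beta[i, t],
                         self.L[i, t])
            for t in range(self.n_times)
        ]


@dataclass(frozen=True)
class ClassThresholds:
    """Movement classification thresholds (K in deg/m, L in m)."""

    K_thresh_bend: float = 20.0
    L_thresh_elong: float = 0.02

    def __post_init__(self):
        if self.K_thresh_bend <= 0 or self.L_thresh_elong <= 0:
            raise KinematicsError("thresholds must be strictly positive")


class MovementClass(Enum):
    B = "B"  # pure bending
    BE = "BE"  # bending + elongation
    OTHER = "OTHER"


@dataclass
class MovementTrial:
    """Time-ordered series of cross-section rows for one recorded movement."""

    sections: list[list[EllipseSection]]  # [time][row]
    sample_rate: float
    label: str | None = None
    n_rows: int = 10
    times: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.sections:
            raise KinematicsError("trial has no samples")
        for t, sample in enumerate(self.sections):
            if len(sample) != self.n_rows:
                raise KinematicsError(
                    f"sample {t} has {len(sample)} rows, expected {self.n_rows}"
                )
            rows = [s.row_index for s in sample]
            if rows != list(range(1, self.n_rows + 1)):
                raise KinematicsError(f"sample {t}: rows out of order: {rows}")
        self.times = np.array([s[0].timestamp for s in self.sections])
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise KinematicsError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise KinematicsError("timestamps must be uniform within 1e-6 s")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def n_times(self) -> int:
        return len(self.sections)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def segment_length(center_i: np.ndarray, center_ip1: np.ndarray) -> float:
    """Segment length: Euclidean distance between consecutive ellipse centers."""
    return float(np.linalg.norm(np.asarray(center_ip1, float) - np.asarray(center_i, float)))


def relative_bend_angles(sec_i: EllipseSection, sec_ip1: EllipseSection) -> tuple[float, float]:
    """Bend angles (deg) between two consecutive section frames.

    The relative rotation ``R_rel = R_i^T R_{i+1}`` is converted to its
    axis-angle (rotation) vector, expressed in section i's frame.  ``alpha``
    is the component about the section's in-plane minor axis (the bending
    axis of dorso-ventral planar movements), ``beta`` the component about
    the in-plane major axis; the component about the plane normal (torsion)
    is discarded.
    """
    R_rel = sec_i.rotation.T @ sec_ip1.rotation
    rotvec = Rotation.from_matrix(R_rel).as_rotvec(degrees=True)
    return float(rotvec[1]), float(rotvec[0])


def segment_curvature(alpha: float, beta: float, L: float,
                      segment_index: int = 0) -> SegmentShape:
    """Curvature components (deg/m) of one segment from its bend angles.

    ``K_alpha = alpha/L``, ``K_beta = beta/L`` and
    ``K = sqrt(K_alpha^2 + K_beta^2)``.
    """
    if L <= 0:
        raise KinematicsError(f"segment {segment_index}: length must be positive")
    K_alpha = alpha / L
    K_beta = beta / L
    return SegmentShape(
        segment_index=segment_index,
        K=float(np.hypot(K_alpha, K_beta)),
        K_alpha=float(K_alpha),
        K_beta=float(K_beta),
        alpha=float(alpha),
        beta=float(beta),
        L=float(L),
    )


def shape_timeseries(trial: MovementTrial) -> ShapeSeries:
    """Segment shape descriptors for every segment and time sample."""
    n_seg = trial.n_rows - 1
    n_t = trial.n_times
    out = {k: np.zeros((n_seg, n_t)) for k in ("K", "K_alpha", "K_beta", "alpha", "beta", "L")}
    for t, sample in enumerate(trial.sections):
        for i in range(n_seg):
            si, sj = sample[i], sample[i + 1]
            L = segment_length(si.center, sj.center)
            a, b = relative_bend_angles(si, sj)
            sh = segment_curvature(a, b, L, segment_index=i + 1)
            out["K"][i, t] = sh.K
            out["K_alpha"][i, t] = sh.K_alpha
            out["K_beta"][i, t] = sh.K_beta
            out["alpha"][i, t] = sh.alpha
            out["beta"][i, t] = sh.beta
            out["L"][i, t] = sh.L
    return ShapeSeries(times=trial.times.copy(), **out)


def classify_movement(shapes: ShapeSeries, th: ClassThresholds | None = None) -> MovementClass:
    """Classify a movement as B, BE or OTHER.

    B: curvature exceeds ``K_thresh_bend`` in at least one segment at some
    time while the maximum segment-length increase (measured against the
    first sample, taken as the rest configuration) stays at or below
    ``L_thresh_elong``.  BE: both thresholds exceeded.  OTHER: curvature
    never crosses its threshold (includes twisting classes, which this
    planar analysis does not separate).
    """
    th = th or ClassThresholds()
    if shapes.n_times == 0:
        raise KinematicsError("empty shape series")
    K_max = float(shapes.K.max())
    dL_max = float((shapes.L - shapes.L[:, :1]).max())
    if K_max > th.K_thresh_bend:
        return MovementClass.BE if dL_max > th.L_thresh_elong else MovementClass.B
    return MovementClass.OTHER


# ---------------------------------------------------------------------------
# ellipse fitting
# ---------------------------------------------------------------------------

def fit_section_ellipse(points: np.ndarray, row_index: int = 0,
                        reference_normal: np.ndarray | None = None,
                        coverage_warn_deg: float = 120.0) -> EllipseSection:
    """Fit a 3D ellipse to >= 5 marker points of one section row.

    The plane is fitted by total least squares (SVD of the centered points),
    the points are projected in-plane, and a direct algebraic ellipse fit is
    performed there.  The returned section frame has its first axis along
    the semi-major axis and its normal along the fitted plane normal
    (flipped toward ``reference_normal`` when given).  ``fit_rms`` is the
    RMS 3D distance of the points from the fitted ellipse.

    Markers covering only a short arc (dorsal-only rows) are accepted, but a
    warning is emitted when the angular coverage around the fitted center is
    ``coverage_warn_deg`` or less, as the fit becomes poorly conditioned.
    """
    from skimage.measure import EllipseModel

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 5:
        raise KinematicsError(
            f"row {row_index}: ellipse fit needs >= 5 3D points, got {pts.shape}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-10 * max(svals[0], 1e-300):
        raise KinematicsError(f"row {row_index}: points are collinear")
    u_ax, v_ax, normal = Vt[0], Vt[1], Vt[2]
    if reference_normal is not None and normal @ np.asarray(reference_normal) < 0:
        normal, v_ax = -normal, -v_ax

    xy = np.column_stack([centered @ u_ax, centered @ v_ax])
    if hasattr(EllipseModel, "from_estimate"):  # scikit-image >= 0.26
        model = EllipseModel.from_estimate(xy)
        if not model:
            raise KinematicsError(f"row {row_index}: degenerate ellipse fit")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:
        model = EllipseModel()
        if not model.estimate(xy):
            raise KinematicsError(f"row {row_index}: degenerate ellipse fit")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise KinematicsError(f"row {row_index}: degenerate ellipse fit")
    if b > a:  # enforce a >= b, rotate frame by 90 deg
        a, b = b, a
        theta += np.pi / 2.0

    center = centroid + xc * u_ax + yc * v_ax
    e_major = np.cos(theta) * u_ax + np.sin(theta) * v_ax
    e_minor = np.cross(normal, e_major)
    R = np.column_stack([e_major, e_minor, normal])

    in_plane = model.residuals(xy)
    out_plane = centered @ normal
    rms = float(np.sqrt(np.mean(in_plane**2 + out_plane**2)))

    # angular coverage of the markers around the fitted center
    rel = xy - np.array([xc, yc])
    ang = np.sort(np.degrees(np.arctan2(rel[:, 1], rel[:, 0])))
    gaps = np.diff(np.r_[ang, ang[0] + 360.0])
    coverage = 360.0 - gaps.max()
    if coverage <= coverage_warn_deg + 1e-9:
        warnings.warn(
            f"row {row_index}: markers cover only {coverage:.1f} deg of the "
            "section ellipse; fit may be poorly conditioned",
            stacklevel=2,
        )

    return EllipseSection.from_rotation(row_index, center, R, (float(a), float(b)),
                                        fit_rms=rms)
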