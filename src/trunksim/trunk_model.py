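"""Discrete trunk structure: point masses, axial rods, assembled matrices.

The trunk is modelled as ``n_sections`` elliptical cross-sections of five
point masses each -- a center node O and four outer nodes at the semi-axis
tips (P dorsal, B lateral, Q ventral, A lateral) -- joined by three families
of axially loaded rods:

* longitudinal rods between same-role outer nodes of adjacent sections
  (muscle analogues driving bending and shortening),
* radial rods from each section center to its four outer nodes
  (muscle analogues narrowing the cross-section),
* connective rods around each section perimeter (passive tissue).

At rest the backbone hangs straight along -Z from a fixed base (gravity acts
along -Z); the dorsal direction is +X and planar reaching happens in the
X-Z plane.  Each rod is a standard 3D truss element: it only transmits
axial force, so its local 6x6 stiffness has a single non-zero mode of
stiffness ``k = E*A/L0``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig

ROLES = ("O", "P", "B", "Q", "A")  # center, dorsal, lateral+, ventral, lateral-
ROD_TYPES = ("longitudinal", "radial", "connective")


class ConfigError(ValueError):
    """Invalid physical configuration."""


@dataclass(frozen=True)
class NodePointMass:
    node_id: int
    section_index: int  # 1-based
    role: str  # one of ROLES
    mass: float  # kg
    rest_position: np.ndarray  # (3,) m

    def __post_init__(self):
        if self.mass <= 0:
            raise ConfigError(f"node {self.node_id}: mass must be positive")
        if self.role not in ROLES:
            raise ConfigError(f"node {self.node_id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Rod:
    rod_id: int
    endpoints: tuple[int, int]
    rod_type: str
    rest_length: float  # m
    youngs_modulus: float  # N/m^2
    area: float  # m^2
    # segment_index for longitudinal rods, section_index otherwise (1-based)
    location_index: int = 0
    role: str = ""  # outer-node role the rod is attached to / runs along

    def __post_init__(self):
        if self.rest_length <= 0:
            raise ConfigError(f"rod {self.rod_id}: non-positive rest length")
        if self.endpoints[0] == self.endpoints[1]:
            raise ConfigError(f"rod {self.rod_id}: coincident endpoints")
        if self.rod_type not in ROD_TYPES:
            raise ConfigError(f"rod {self.rod_id}: unknown type {self.rod_type!r}")

    @property
    def axial_stiffness(self) -> float:
        """k = E*A/L0, N/m."""
        return self.youngs_modulus * self.area / self.rest_length


@dataclass
class TrunkStructure:
    """Assembled discrete trunk (or any pin-jointed truss of point masses)."""

    nodes: list[NodePointMass]
    rods: list[Rod]
    fixed_nodes: frozenset[int]
    total_mass: float
    total_length: float
    n_sections: int
    config: RunConfig | None = None
    _rod_lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        msum = sum(nd.mass for nd in self.nodes)
        if not np.isclose(msum, self.total_mass, rtol=1e-9):
            raise ConfigError(
                f"node masses sum to {msum!r}, expected {self.total_mass!r}"
            )
        self._rod_lookup = {}
        for rod in self.rods:
            self._rod_lookup[(rod.rod_type, rod.location_index, rod.role)] = rod.rod_id

    # -- basic sizes -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_dof(self) -> int:
        return 3 * self.n_nodes

    @property
    def n_segments(self) -> int:
        return self.n_sections - 1

    @property
    def n_rods(self) -> int:
        return len(self.rods)

    # -- lookups -----------------------------------------------------------
    def node_id(self, section_index: int, role: str) -> int:
        return 5 * (section_index - 1) + ROLES.index(role)

    def rod_id(self, rod_type: str, location_index: int, role: str) -> int:
        """Rod id by (type, segment-or-section index, role)."""
        return self._rod_lookup[(rod_type, location_index, role)]

    def rest_positions(self) -> np.ndarray:
        return np.array([nd.rest_position for nd in self.nodes])

    def masses(self) -> np.ndarray:
        return np.array([nd.mass for nd in self.nodes])

    def free_dof_mask(self) -> np.ndarray:
        mask = np.ones(self.n_dof, dtype=bool)
        for nid in self.fixed_nodes:
            mask[3 * nid : 3 * nid + 3] = False
        return mask

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "total_mass": self.total_mass,
            "total_length": self.total_length,
            "n_sections": self.n_sections,
            "fixed_nodes": sorted(self.fixed_nodes),
            "config": self.config.model_dump() if self.config else None,
            "nodes": [
                {
                    "node_id": nd.node_id,
                    "section_index": nd.section_index,
                    "role": nd.role,
                    "mass": nd.mass,
                    "rest_position": list(nd.rest_position),
                }
                for nd in self.nodes
            ],
            "rods": [
                {
                    "rod_id": r.rod_id,
                    "endpoints": list(r.endpoints),
                    "rod_type": r.rod_type,
                    "rest_length": r.rest_length,
                    "youngs_modulus": r.youngs_modulus,
                    "area": r.area,
                    "location_index": r.location_index,
                    "role": r.role,
                }
                for r in self.rods
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrunkStructure":
        payload = json.loads(Path(path).read_text())
        nodes = [
            NodePointMass(
                node_id=d["node_id"],
                section_index=d["section_index"],
                role=d["role"],
                mass=d["mass"],
                rest_position=np.array(d["rest_position"], dtype=float),
            )
            for d in payload["nodes"]
        ]
        rods = [
            Rod(
                rod_id=d["rod_id"],
                endpoints=tuple(d["endpoints"]),
                rod_type=d["rod_type"],
                rest_length=d["rest_length"],
                youngs_modulus=d["youngs_modulus"],
                area=d["area"],
                location_index=d["location_index"],
                role=d["role"],
            )
            for d in payload["rods"]
        ]
        config = RunConfig(**payload["config"]) if payload.get("config") else None
        return cls(
            nodes=nodes,
            rods=rods,
            fixed_nodes=frozenset(payload["fixed_nodes"]),
            total_mass=payload["total_mass"],
            total_length=payload["total_length"],
            n_sections=payload["n_sections"],
            config=config,
        )


# ---------------------------------------------------------------------------
# mass distribution
# ---------------------------------------------------------------------------

def frustum_volume(r1: float, r2: float, h: float) -> float:
    """Volume of a truncated cone: (pi*h/3)(r1^2 + r1*r2 + r2^2)."""
    return np.pi * h / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)


def distribute_mass(
    total_mass: float, section_radii: np.ndarray, section_length: float
) -> np.ndarray:
    """Allocate the total trunk mass to the node point masses.

    The trunk is sliced into ``len(section_radii)-1`` truncated-cone
    sub-volumes (radii at the slice stations); each slice's share of the
    total mass is proportional to its frustum volume, and is then split
    equally among the five nodes of the corresponding cross-section.

    Returns a flat array of ``5*(len(section_radii)-1)`` node masses whose
    sum is exactly ``total_mass``.
    """
    radii = np.asarray(section_radii, dtype=float)
    if total_mass <= 0 or section_length <= 0:
        raise ConfigError("total_mass and section_length must be positive")
    if np.any(radii <= 0):
        raise ConfigError("section radii must be positive")
    if np.any(np.diff(radii) > 1e-12):
        warnings.warn("section radii are not monotone non-increasing base->tip")
    vols = frustum_volume(radii[:-1], radii[1:], section_length)
    section_masses = total_mass * vols / vols.sum()
    node_masses = np.repeat(section_masses / 5.0, 5)
    # remove float round-off so the invariant is exact
    node_masses *= total_mass / node_masses.sum()
    return node_masses


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def local_stiffness_matrix(k: float) -> np.ndarray:
    """6x6 local stiffness of an axial truss rod (local x along the rod)."""
    if k <= 0:
        raise ConfigError("axial stiffness must be positive")
    K = np.zeros((6, 6))
    K[0, 0] = K[3, 3] = k
    K[0, 3] = K[3, 0] = -k
    return K


def _frame_from_axis(u: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal 3x3 whose FIRST ROW is the unit vector u."""
    u = u / np.linalg.norm(u)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(helper, u)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.vstack([u, v, w])


def rod_rotation_matrix(rod: Rod, node_positions: np.ndarray) -> np.ndarray:
    """6x6 local->global transformation, block-diagonal pair of direction
    cosine matrices; first row of each block is the rod's unit vector."""
    i, j = rod.endpoints
    d = np.asarray(node_positions)[j] - np.asarray(node_positions)[i]
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ConfigError(f"rod {rod.rod_id}: zero length at current positions")
    block = _frame_from_axis(d)
    R = np.zeros((6, 6))
    R[:3, :3] = block
    R[3:, 3:] = block
    return R


def globalize_stiffness(K_loc: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Transform an element stiffness to the global frame: R^T K_loc R."""
    return R.T @ K_loc @ R


def assemble_global(structure: TrunkStructure) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the global stiffness and (diagonal) mass matrices.

    Element matrices are built in the rest configuration and scatter-added
    into the 3-DoF-per-node global slots; the stiffness is not updated with
    deformation (small-strain passive elasticity).  Returns
    ``(K_glob, M_diag)`` with shapes (3N, 3N) each; the mass matrix carries
    each node mass three times along the diagonal.
    """
    n = structure.n_dof
    K = np.zeros((n, n))
    pos = structure.rest_positions()
    for rod in structure.rods:
        Ke = globalize_stiffness(
            local_stiffness_matrix(rod.axial_stiffness),
            rod_rotation_matrix(rod, pos),
        )
        i, j = rod.endpoints
        dofs = np.r_[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
        K[np.ix_(dofs, dofs)] += Ke
    M = np.diag(np.repeat(structure.masses(), 3))
    return K, M


# ---------------------------------------------------------------------------
# structure builder
# ---------------------------------------------------------------------------

def _section_region(segment_index: int, n_segments: int) -> str:
    """Map a 1-based segment index to the proximal/middle/distal third."""
    third = max(1, int(np.ceil(n_segments / 3)))
    if segment_index <= third:
        return "proximal"
    if segment_index <= 2 * third:
        return "middle"
    return "distal"


def build_structure(config: RunConfig | None = None, **overrides) -> TrunkStructure:
    """Build the discrete trunk from physical parameters.

    The default configuration yields 50 nodes in 10 sections (9 segments of
    ~0.2 m), 150 degrees of freedom, node masses summing to 100 kg and all
    five nodes of the base section fixed.  Cross-sections are circular at
    rest with radius tapering linearly from ``base_radius`` to
    ``tip_radius``.
    """
    if config is None:
        config = RunConfig(**overrides)
    elif overrides:
        config = RunConfig(**{**config.model_dump(), **overrides})

    ns = config.n_sections
    nseg = ns - 1
    seg_len = config.segment_rest_length
    E = config.youngs_modulus
    frac = config.area_fractions

    # section radii (node placement) and mass-slice radii (ns+1 stations)
    sec_radii = np.linspace(config.base_radius, config.tip_radius, ns)
    slice_radii = np.linspace(config.base_radius, config.tip_radius, ns + 1)
    node_masses = distribute_mass(config.total_mass, slice_radii, seg_len)

    dorsal = np.array([1.0, 0.0, 0.0])
    lateral = np.array([0.0, 1.0, 0.0])
    axis = np.array([0.0, 0.0, -1.0])  # hanging rest backbone

    nodes: list[NodePointMass] = []
    for s in range(1, ns + 1):
        c = (s - 1) * seg_len * axis
        r = sec_radii[s - 1]
        offsets = {
            "O": np.zeros(3),
            "P": r * dorsal,
            "B": r * lateral,
            "Q": -r * dorsal,
            "A": -r * lateral,
        }
        for role in ROLES:
            nid = 5 * (s - 1) + ROLES.index(role)
            nodes.append(
                NodePointMass(
                    node_id=nid,
                    section_index=s,
                    role=role,
                    mass=float(node_masses[nid]),
                    rest_position=c + offsets[role],
                )
            )

    def section_E(s: int) -> float:
        seg = min(s, nseg)
        return getattr(E, _section_region(seg, nseg))

    def cross_area(s: int) -> float:
        r = sec_radii[s - 1]
        return np.pi * r * r

    pos = np.array([nd.rest_position for nd in nodes])
    rods: list[Rod] = []

    def add_rod(rtype: str, i: int, j: int, area: float, Eval: float,
                loc: int, role: str) -> None:
        L0 = float(np.linalg.norm(pos[j] - pos[i]))
        rods.append(
            Rod(
                rod_id=len(rods),
                endpoints=(i, j),
                rod_type=rtype,
                rest_length=L0,
                youngs_modulus=Eval,
                area=area,
                location_index=loc,
                role=role,
            )
        )

    perimeter = [("P", "B"), ("B", "Q"), ("Q", "A"), ("A", "P")]
    for s in range(1, ns + 1):
        O = 5 * (s - 1)
        a = cross_area(s)
        for role in ("P", "B", "Q", "A"):
            add_rod("radial", O, O + ROLES.index(role), frac.radial * a,
                    section_E(s), s, role)
        for r1, r2 in perimeter:
            add_rod("connective", O + ROLES.index(r1), O + ROLES.index(r2),
                    frac.connective * a, section_E(s), s, r1 + r2)
    for seg in range(1, nseg + 1):
        a = 0.5 * (cross_area(seg) + cross_area(seg + 1))
        Eval = getattr(E, _section_region(seg, nseg))
        for role in ("P", "B", "Q", "A"):
            i = 5 * (seg - 1) + ROLES.index(role)
            add_rod("longitudinal", i, i + 5, frac.longitudinal * a, Eval,
                    seg, role)
        if config.connective_web:
            # diagonal connective-tissue web: center of one section to the
            # outer nodes of the next, both directions.  These passive
            # members give the straight trunk first-order bending
            # stiffness/authority and carry the center nodes axially.
            O_lo = 5 * (seg - 1)
            O_hi = 5 * seg
            for role in ("P", "B", "Q", "A"):
                ri = ROLES.index(role)
                add_rod("connective", O_lo, O_hi + ri, frac.web * a, Eval,
                        seg, f"O{role}")
                add_rod("connective", O_lo + ri, O_hi, frac.web * a, Eval,
                        seg, f"{role}O")

    fixed = frozenset(range(5)) if config.fixed_base else frozenset()
    return TrunkStructure(
        nodes=nodes,
        rods=rods,
        fixed_nodes=fixed,
        total_mass=config.total_mass,
        total_length=config.total_length,
        n_sections=ns,
        config=config,
    )


def section_node_positions_from_ellipse(center: np.ndarray, rotation: np.ndarray,
                                        semi_axes: tuple[float, float]) -> np.ndarray:
    """Positions of the five section nodes (O,P,B,Q,A) implied by an ellipse.

    ``rotation`` columns are (dorsal axis, lateral axis, normal); outer nodes
    sit at the semi-axis tips.
    """
    a, b = semi_axes
    e1, e2 = rotation[:, 0], rotation[:, 1]
    return np.array([center, center + a * e1, center + b * e2,
                     center - a * e1, center - b * e2])
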