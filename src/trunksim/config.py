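"""Run configuration: physical parameters, thresholds and solver settings.

The schema is strict — unknown keys are rejected — because the model carries
many physical constants and a silently ignored typo (``youngs_modulos``)
would be indistinguishable from a deliberate default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class StiffnessProfile(BaseModel):
    """Young's modulus (N/m^2) per trunk region.

    The trunk is split into three regions of three segments each
    (proximal = segments 1-3, middle = 4-6, distal = 7-9).  The default is a
    uniform apparent modulus of 1e6 N/m^2, an estimate for muscular-hydrostat
    tissue; decreasing base-to-tip profiles can be configured.
    """

    model_config = ConfigDict(extra="forbid")

    proximal: float = Field(1.0e6, gt=0)
    middle: float = Field(1.0e6, gt=0)
    distal: float = Field(1.0e6, gt=0)


class AreaFractions(BaseModel):
    """Effective rod cross-section areas as fractions of the local
    cross-section area (pi*a*b).  The rods are muscle-analogue force paths,
    not anatomical muscles; the fractions set the passive axial stiffness
    k = E*A/L0 of each rod type.  ``web`` applies to the diagonal
    connective-tissue rods joining adjacent sections."""

    model_config = ConfigDict(extra="forbid")

    longitudinal: float = Field(0.15, gt=0, le=1)
    radial: float = Field(0.10, gt=0, le=1)
    connective: float = Field(0.05, gt=0, le=1)
    web: float = Field(0.05, gt=0, le=1)


class SolverConfig(BaseModel):
    """Numerical settings for integration and per-step force estimation."""

    model_config = ConfigDict(extra="forbid")

    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-9, gt=0)
    force_bound: float = Field(5000.0, gt=0)  # N, upper bound per unknown
    # lower bound on the active rod forces.  Muscles pull, so pushing is
    # limited: the surrounding tissue can transmit moderate compression,
    # but past ~1.5 kN the compressed rod columns of this truss buckle.
    force_bound_lower: float = Field(-1000.0)
    opt_tol: float = Field(1e-8, gt=0)  # ftol/xtol/gtol of least squares
    max_iterations: int = Field(200, gt=0)  # per estimation step
    diff_step: float = Field(1.0, gt=0)  # N, finite-difference step on forces
    force_scale: float = Field(100.0, gt=0)  # N, optimizer variable scaling
    # weight of the minimum-norm tie-break: residual sqrt(ridge)*f/force_bound
    # per unknown.  Keeps the under-observed force directions from wandering
    # to the bounds while costing well-observed directions < 1 mm equivalent.
    ridge: float = Field(1e-5, ge=0)
    # preferred resting force level (N) the minimum-norm tie-break pulls
    # estimates toward (0 = plain minimum norm); a positive muscle tonus
    # models baseline co-contraction
    tonus: float = Field(0.0, ge=0)


class RunConfig(BaseModel):
    """Top-level configuration of the trunk model and analysis pipeline."""

    model_config = ConfigDict(extra="forbid")

    total_mass: float = Field(100.0, gt=0)  # kg
    total_length: float = Field(1.85, gt=0)  # m, 9 modelled segments
    n_sections: int = Field(10, ge=2)
    base_radius: float = Field(0.15, gt=0)  # m, assumed
    tip_radius: float = Field(0.05, gt=0)  # m, trunk-tip radius
    youngs_modulus: StiffnessProfile = Field(default_factory=StiffnessProfile)
    area_fractions: AreaFractions = Field(default_factory=AreaFractions)
    gravity: float = Field(9.81, ge=0)  # m/s^2, acts along -Z
    damping: float = Field(2.0, ge=0)  # 1/s, mass-proportional viscous term
    axial_damping: float = Field(0.01, ge=0)  # s, Kelvin-Voigt rod dashpot
    k_thresh_bend: float = Field(20.0, gt=0)  # deg/m
    l_thresh_elong: float = Field(0.02, gt=0)  # m
    sample_rate: float = Field(100.0, gt=0)  # Hz
    seed: int = Field(0, ge=0)
    fixed_base: bool = True  # clamp all five nodes of section 1
    fr_split: Literal["four-way", "dorso-ventral"] = "four-way"
    lateral_longitudinal: Literal["mirrored", "passive"] = "mirrored"
    # diagonal connective-tissue rods between adjacent sections; without
    # them the straight rest configuration has no first-order bending
    # stiffness or authority and the backbone centers hang unsupported
    connective_web: bool = True
    solver: SolverConfig = Field(default_factory=SolverConfig)

    @model_validator(mode="after")
    def _check_taper(self) -> "RunConfig":
        if self.tip_radius > self.base_radius:
            raise ValueError(
                "tip_radius must not exceed base_radius (taper is base->tip)"
            )
        return self

    @property
    def n_segments(self) -> int:
        return self.n_sections - 1

    @property
    def segment_rest_length(self) -> float:
        """Rest length of one segment (m); 1.85/9 ~ 0.2056 by default."""
        return self.total_length / self.n_segments

    def config_hash(self) -> str:
        """Stable hash of the configuration, for run logs."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file, fill defaults, validate strictly.

    An empty or missing file yields the full default configuration.
    Unknown keys, wrong types or non-positive physical values raise a
    ``pydantic.ValidationError`` naming the offending key path.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config root must be a mapping, got {type(loaded)}")
            data = loaded
    data.update(overrides)
    return RunConfig(**data)
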