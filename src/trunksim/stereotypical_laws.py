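"""Stereotypical force-shape laws: per-segment multilinear regressions.

For every trunk segment, three linear laws relate the shape variables --
curvature ``K`` (deg/m) and length ``L`` (m) -- to the internal force
aggregates ``dFL`` (dorsal minus ventral longitudinal force, the bending
drive), ``FR`` (radial force, the narrowing/elongation drive) and ``Fm_L``
(mean longitudinal force, the axial drive), all in N:

    K-law:  K  = b0 + b1*dFL + b2*FR + b3*Fm_L + e
    L-law:  L  = b0 + b1*dFL + b2*FR + b3*Fm_L + e
    F-law:  FR = b0 + b1*dFL + b3*Fm_L + e

Coefficients are ordinary least squares estimates; fit quality is reported
as R^2, adjusted R^2 and RMSE.  The three laws of a segment form a
determined 3x3 linear system in (dFL, FR, Fm_L): given a desired (K, L)
the system is inverted to obtain the internal forces that produce it --
the basis of the open-loop reaching controller.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LawCoefficients",
    "LawSet",
    "LawError",
    "fit_multilinear",
    "fit_segment_laws",
    "pairwise_correlations",
    "solve_forces_from_shape",
]

LAW_IDS = ("K-law", "L-law", "F-law")
COND_LIMIT = 1e12


class LawError(ValueError):
    pass


@dataclass
class LawCoefficients:
    """OLS coefficients and fit statistics of one per-segment law."""

    law_id: str
    segment_index: int
    beta: np.ndarray  # (p+1,) intercept first
    residual_sd: float
    r2: float
    r2_adj: float
    rmse: float
    n_samples: int

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        if self.law_id not in LAW_IDS:
            raise LawError(f"unknown law id {self.law_id!r}")

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.beta[0] + X @ self.beta[1:]


@dataclass
class LawSet:
    """Complete set of fitted laws: one (K, L, F) triple per segment."""

    laws: dict  # (law_id, segment_index) -> LawCoefficients
    n_segments: int
    movement_class: str | None = None
    provenance: dict = field(default_factory=dict)

    def law(self, law_id: str, segment_index: int) -> LawCoefficients:
        return self.laws[(law_id, segment_index)]

    def is_complete(self) -> bool:
        return all((lid, s) in self.laws
                   for lid in LAW_IDS for s in range(1, self.n_segments + 1))

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_segments": self.n_segments,
            "movement_class": self.movement_class,
            "provenance": self.provenance,
            "laws": [
                {
                    "law_id": lc.law_id,
                    "segment_index": lc.segment_index,
                    "beta": list(lc.beta),
                    "residual_sd": lc.residual_sd,
                    "r2": lc.r2,
                    "r2_adj": lc.r2_adj,
                    "rmse": lc.rmse,
                    "n_samples": lc.n_samples,
                }
                for lc in self.laws.values()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LawSet":
        payload = json.loads(Path(path).read_text())
        laws = {}
        for d in payload["laws"]:
            lc = LawCoefficients(
                law_id=d["law_id"], segment_index=d["segment_index"],
                beta=np.array(d["beta"]), residual_sd=d["residual_sd"],
                r2=d["r2"], r2_adj=d["r2_adj"], rmse=d["rmse"],
                n_samples=d["n_samples"])
            laws[(lc.law_id, lc.segment_index)] = lc
        return cls(laws=laws, n_segments=payload["n_segments"],
                   movement_class=payload.get("movement_class"),
                   provenance=payload.get("provenance", {}))


def fit_multilinear(y: np.ndarray, X: np.ndarray, law_id: str = "K-law",
                    segment_index: int = 0,
                    predictor_names: tuple[str, ...] | None = None) -> LawCoefficients:
    """Ordinary least squares fit of ``y = b0 + X @ b + e``.

    ``X`` has shape (n, p) with p <= 3 predictors.  Raises
    :class:`LawError` on rank-deficient designs, naming the offending
    predictors (constant or collinear columns).
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y) and X.shape[1] == len(y):
        X = X.T  # accept (p, n) predictor stacks
    n, p = X.shape
    if n != len(y):
        raise LawError("y and X lengths differ")
    if n <= p + 1:
        raise LawError(f"need more than {p + 1} samples, got {n}")
    names = predictor_names or tuple(f"X{i+1}" for i in range(p))

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        bad = [names[i] for i in range(p) if np.ptp(X[:, i]) == 0.0]
        detail = f"constant predictors: {bad}" if bad else "collinear predictors"
        raise LawError(f"singular design for {law_id} segment {segment_index}: "
                       f"{detail} among {list(names)}")
    fit = sm.OLS(y, design).fit()
    resid = y - fit.fittedvalues
    rmse = float(np.sqrt(np.mean(resid**2)))
    dof = n - p - 1
    return LawCoefficients(
        law_id=law_id, segment_index=segment_index,
        beta=np.asarray(fit.params, float),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        rmse=rmse, n_samples=n)


def fit_segment_laws(K: np.ndarray, L: np.ndarray, dfl: np.ndarray,
                     fr: np.ndarray, fml: np.ndarray,
                     movement_class: str | None = None,
                     provenance: dict | None = None) -> LawSet:
    """Fit the K-, L- and F-laws of every segment.

    All inputs are (n_samples, n_segments) arrays of aligned time samples
    (one or more trials concatenated along axis 0).
    """
    arrs = [np.atleast_2d(np.asarray(a, float)) for a in (K, L, dfl, fr, fml)]
    if len({a.shape for a in arrs}) != 1:
        raise LawError("all variable arrays must share the same shape")
    K, L, dfl, fr, fml = arrs
    n_seg = K.shape[1]
    laws = {}
    for s in range(1, n_seg + 1):
        i = s - 1
        X3 = np.column_stack([dfl[:, i], fr[:, i], fml[:, i]])
        laws[("K-law", s)] = fit_multilinear(
            K[:, i], X3, "K-law", s, ("dFL", "FR", "FmL"))
        laws[("L-law", s)] = fit_multilinear(
            L[:, i], X3, "L-law", s, ("dFL", "FR", "FmL"))
        laws[("F-law", s)] = fit_multilinear(
            fr[:, i], np.column_stack([dfl[:, i], fml[:, i]]),
            "F-law", s, ("dFL", "FmL"))
    return LawSet(laws=laws, n_segments=n_seg, movement_class=movement_class,
                  provenance=provenance or {})


VARIABLE_ORDER = ("K", "L", "FR", "dFL", "FmL")


def pairwise_correlations(K, L, fr, dfl, fml) -> pd.DataFrame:
    """Pearson correlation matrix among the five per-segment variables.

    Zero-variance variables yield NaN rows/columns and a warning rather
    than a division error.
    """
    data = {name: np.asarray(v, float).ravel()
            for name, v in zip(VARIABLE_ORDER, (K, L, fr, dfl, fml))}
    n = len(next(iter(data.values())))
    if any(len(v) != n for v in data.values()):
        raise LawError("all series must have equal length")
    mat = np.empty((5, 5))
    sds = {k: v.std() for k, v in data.items()}
    for k, sd in sds.items():
        if sd == 0.0:
            warnings.warn(f"variable {k} has zero variance; correlations undefined")
    for i, a in enumerate(VARIABLE_ORDER):
        for j, b in enumerate(VARIABLE_ORDER):
            if i == j:
                mat[i, j] = 1.0
            elif sds[a] == 0.0 or sds[b] == 0.0:
                mat[i, j] = np.nan
            else:
                mat[i, j] = np.corrcoef(data[a], data[b])[0, 1]
    return pd.DataFrame(mat, index=VARIABLE_ORDER, columns=VARIABLE_ORDER)


def solve_forces_from_shape(K_i: float, L_i: float, laws: LawSet,
                            segment_index: int) -> tuple[float, float, float]:
    """Invert the determined 3x3 law system of one segment.

    Given a desired curvature ``K_i`` (deg/m) and length ``L_i`` (m),
    solves

        b1K*dFL + b2K*FR + b3K*FmL = K_i - b0K
        b1L*dFL + b2L*FR + b3L*FmL = L_i - b0L
        -b1F*dFL +     FR - b3F*FmL = b0F

    for ``(dFL, FR, Fm_L)`` in N.  Raises :class:`LawError` when laws are
    missing or the system's condition number exceeds 1e12.
    """
    for lid in LAW_IDS:
        if (lid, segment_index) not in laws.laws:
            raise LawError(f"law set incomplete: missing {lid} for segment {segment_index}")
    bK = laws.law("K-law", segment_index).beta
    bL = laws.law("L-law", segment_index).beta
    bF = laws.law("F-law", segment_index).beta
    A = np.array([
        [bK[1], bK[2], bK[3]],
        [bL[1], bL[2], bL[3]],
        [-bF[1], 1.0, -bF[2]],
    ])
    rhs = np.array([K_i - bK[0], L_i - bL[0], bF[0]])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise LawError(
            f"law system of segment {segment_index} is singular or "
            f"ill-conditioned (cond={cond:.3g})")
    dfl, fr, fml = np.linalg.solve(A, rhs)
    return float(dfl), float(fr), float(fml)
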