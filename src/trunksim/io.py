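"""CSV/JSON readers and writers for trials, markers, forces and trajectories.

All CSV files use comma separators, '.' decimals, a mandatory header row and
UTF-8; floats are written with 17 significant digits so round trips are
bit-exact for finite values.

Trial dialect (one line per section per sample):
    time, row_index, cx, cy, cz, ez, ey, ex, semi_a, semi_b
with centers in meters and ZYX-intrinsic Euler angles in radians.

Marker dialect: ``time, row_index, marker_id, x, y, z``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import EllipseSection, MovementTrial

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "write_trial_json",
    "read_trial_json",
    "read_marker_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_force_history_csv",
    "read_force_schedule_csv",
    "load_deposited_trial",
]

TRIAL_COLUMNS = ["time", "row_index", "cx", "cy", "cz", "ez", "ey", "ex",
                 "semi_a", "semi_b"]
_FFMT = "%.17g"


class FormatError(ValueError):
    """Malformed input file."""


def _trial_frame(trial: MovementTrial) -> pd.DataFrame:
    rows = []
    for t, sample in enumerate(trial.sections):
        for sec in sample:
            rows.append([trial.times[t], sec.row_index, *sec.center,
                         *sec.euler_zyx, *sec.semi_axes])
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trial_csv(trial: MovementTrial, path: str | Path) -> None:
    _trial_frame(trial).to_csv(path, index=False, float_format=_FFMT)


def _trial_from_frame(df: pd.DataFrame, sample_rate: float | None,
                      label: str | None) -> MovementTrial:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table is missing columns {missing}")
    n_rows = int(df["row_index"].max())
    times = np.sort(df["time"].unique())
    if sample_rate is None:
        if len(times) < 2:
            raise FormatError("sample_rate required for single-sample trials")
        sample_rate = 1.0 / float(np.mean(np.diff(times)))
    samples = []
    for t in times:
        block = df[df["time"] == t].sort_values("row_index")
        if list(block["row_index"]) != list(range(1, n_rows + 1)):
            raise FormatError(
                f"sample at t={t}: expected rows 1..{n_rows}, got "
                f"{list(block['row_index'])}")
        sample = [
            EllipseSection(
                row_index=int(r.row_index),
                center=np.array([r.cx, r.cy, r.cz]),
                euler_zyx=np.array([r.ez, r.ey, r.ex]),
                semi_axes=(float(r.semi_a), float(r.semi_b)),
                timestamp=float(r.time),
            )
            for r in block.itertuples()
        ]
        samples.append(sample)
    return MovementTrial(sections=samples, sample_rate=float(sample_rate),
                         label=label, n_rows=n_rows)


def read_trial_csv(path: str | Path, sample_rate: float | None = None,
                   label: str | None = None) -> MovementTrial:
    return _trial_from_frame(pd.read_csv(path, float_precision="round_trip"), sample_rate, label)


def write_trial_json(trial: MovementTrial, path: str | Path) -> None:
    payload = {
        "sample_rate": trial.sample_rate,
        "label": trial.label,
        "n_rows": trial.n_rows,
        "samples": [
            [
                {
                    "row_index": sec.row_index,
                    "center": list(sec.center),
                    "euler_zyx": list(sec.euler_zyx),
                    "semi_axes": list(sec.semi_axes),
                    "timestamp": sec.timestamp,
                }
                for sec in sample
            ]
            for sample in trial.sections
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_trial_json(path: str | Path) -> MovementTrial:
    payload = json.loads(Path(path).read_text())
    samples = [
        [
            EllipseSection(
                row_index=d["row_index"], center=np.array(d["center"]),
                euler_zyx=np.array(d["euler_zyx"]),
                semi_axes=tuple(d["semi_axes"]), timestamp=d["timestamp"])
            for d in sample
        ]
        for sample in payload["samples"]
    ]
    return MovementTrial(sections=samples, sample_rate=payload["sample_rate"],
                         label=payload.get("label"), n_rows=payload["n_rows"])


def read_marker_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["time", "row_index", "marker_id", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"marker table is missing columns {missing}")
    return df


def write_trajectory_csv(positions: np.ndarray, times: np.ndarray,
                         path: str | Path) -> None:
    """Node trajectory (n_times, n_nodes, 3) to tidy CSV."""
    T, N, _ = positions.shape
    df = pd.DataFrame({
        "time": np.repeat(times, N),
        "node_id": np.tile(np.arange(N), T),
        "x": positions[:, :, 0].ravel(),
        "y": positions[:, :, 1].ravel(),
        "z": positions[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False, float_format=_FFMT)


def read_trajectory_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    times = np.sort(df["time"].unique())
    n_nodes = int(df["node_id"].max()) + 1
    out = np.zeros((len(times), n_nodes, 3))
    for ti, t in enumerate(times):
        block = df[df["time"] == t].sort_values("node_id")
        out[ti] = block[["x", "y", "z"]].to_numpy()
    return out, times


def write_force_history_csv(history, path: str | Path) -> None:
    history.to_frame().to_csv(path, index=False, float_format=_FFMT)


def read_force_schedule_csv(path: str | Path) -> pd.DataFrame:
    """Per-rod force schedule: columns time, rod_id, force."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time", "rod_id", "force") if c not in df.columns]
    if missing:
        raise FormatError(f"force schedule is missing columns {missing}")
    return df


def load_deposited_trial(path: str | Path, sample_rate: float | None = None,
                         n_rows_expected: int = 10) -> MovementTrial:
    """Load one trial from a local copy of the deposited mocap dataset.

    Expects the per-trial ellipse table layout (the dialect of
    :func:`read_trial_csv`): one line per section row per time sample with
    3D centers (m), ZYX Euler angles (rad) and semi-axes (m).  Files are
    never downloaded here; point ``path`` at a local extraction.  Raises a
    descriptive :class:`FormatError` on missing rows or columns.
    """
    trial = read_trial_csv(path, sample_rate=sample_rate)
    if trial.n_rows != n_rows_expected:
        raise FormatError(
            f"deposited trial has {trial.n_rows} section rows per sample, "
            f"expected {n_rows_expected}")
    return trial
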