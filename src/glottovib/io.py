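"""On-disk formats: trajectory CSVs, cohort tables, frame stacks, exports.

Edge trajectories are stored long-format with the exact header
``frame,position,left_width,right_width`` plus a sidecar JSON (same path
with a ``.json`` suffix) carrying ``fps``, ``fold_length``, ``units``, and
``involved_side``.  Frame stacks are directories of zero-padded 8-bit
grayscale PNGs with a ``metadata.json`` sidecar.  Numeric round trips are
lossless at 6 significant digits.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .kymography import Kymogram
from .render import FrameStack
from .trajectory import EdgeTrajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_cohort",
    "read_cohort",
    "write_frame_stack",
    "read_frame_stack",
    "write_kymogram_csv",
]

TRAJECTORY_COLUMNS = ["frame", "position", "left_width", "right_width"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trajectory(traj: EdgeTrajectory, path) -> None:
    """Write a trajectory as long-format CSV plus metadata sidecar."""
    path = Path(path)
    n_f, n_p = traj.widths_left.shape
    frames = np.repeat(np.arange(n_f), n_p)
    positions = np.tile(traj.positions, n_f)
    df = pd.DataFrame(
        {
            "frame": frames,
            "position": positions,
            "left_width": traj.widths_left.ravel(),
            "right_width": traj.widths_right.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    meta = {
        "fps": traj.fps,
        "fold_length": traj.fold_length,
        "units": traj.units,
        "involved_side": traj.involved_side,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_trajectory(path) -> EdgeTrajectory:
    """Read a trajectory CSV + sidecar written by :func:`write_trajectory`.

    Raises
    ------
    FormatError
        On a missing sidecar or a header deviating from
        ``frame,position,left_width,right_width`` (names the first missing
        column).
    ValidationError
        On negative widths (names the offending data row).
    """
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())

    df = pd.read_csv(path)
    for col in TRAJECTORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trajectory CSV missing column {col!r}")

    for col in ("left_width", "right_width"):
        bad = np.nonzero(df[col].to_numpy(float) < 0)[0]
        if len(bad):
            raise ValidationError(
                f"negative {col} at data row {int(bad[0])}"
            )

    pivot_l = df.pivot(index="frame", columns="position", values="left_width")
    pivot_r = df.pivot(index="frame", columns="position", values="right_width")
    positions = pivot_l.columns.to_numpy(float)
    return EdgeTrajectory(
        widths_left=pivot_l.to_numpy(float),
        widths_right=pivot_r.to_numpy(float),
        fps=float(meta["fps"]),
        positions=positions,
        fold_length=float(meta["fold_length"]),
        units=meta["units"],
        involved_side=meta.get("involved_side"),
    )


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort parameter table (one row per subject)."""
    table.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "diagnosis"):
        if col not in df.columns:
            raise FormatError(f"cohort CSV missing column {col!r}")
    return df


def write_frame_stack(stack: FrameStack, directory) -> None:
    """Write PNG frames ``frame_00000.png`` ... plus ``metadata.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(stack.n_frames):
        iio.imwrite(directory / f"frame_{t:05d}.png", stack.frames[t])
    meta = dict(stack.meta)
    meta["fps"] = stack.fps
    meta["n_frames"] = stack.n_frames
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def read_frame_stack(directory) -> FrameStack:
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise FormatError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FormatError(f"no frame PNGs in {directory}")
    frames = np.stack([iio.imread(p) for p in paths])
    fps = float(meta.pop("fps"))
    meta.pop("n_frames", None)
    return FrameStack(frames=frames, fps=fps, meta=meta)


def write_kymogram_csv(kymo: Kymogram, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(kymo.left)), "left_width": kymo.left, "right_width": kymo.right}
    ).to_csv(path, index=False, float_format="%.6g")
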