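"""Reading and writing detection/trajectory tables.

File dialect: UTF-8 CSV, comma-separated, '.' decimal, required header row.

* detections CSV: columns ``channel,frame,x,y,intensity``
* trajectories CSV: columns
  ``traj_id,cell_id,condition,frame,acc_x,acc_y,don_x,don_y,acc_intensity,don_intensity``

An HDF5 mirror of the trajectory layout is provided for large datasets
(one group per trajectory, arrays as datasets, identifiers as attributes).
"""

from __future__ import annotations

import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import (
    CHANNELS,
    Detection,
    DonorAcceptorTrajectory,
    FormatError,
    ValidationError,
)

DETECTION_COLUMNS = ["channel", "frame", "x", "y", "intensity"]
TRAJECTORY_COLUMNS = [
    "traj_id",
    "cell_id",
    "condition",
    "frame",
    "acc_x",
    "acc_y",
    "don_x",
    "don_y",
    "acc_intensity",
    "don_intensity",
]


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    got = list(df.columns)
    if got != expected:
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        raise FormatError(
            f"{path}: expected columns {expected}, got {got}"
            f" (missing {missing}, extra {extra})"
        )


def read_detections(path, channel: str | None = None) -> list[Detection]:
    """Read a detections CSV, optionally keeping a single channel.

    Row order is preserved.  Non-finite coordinates raise a
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, DETECTION_COLUMNS, path)
    out: list[Detection] = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        if channel is not None and row.channel != channel:
            continue
        try:
            out.append(
                Detection(
                    channel=str(row.channel),
                    frame=int(row.frame),
                    x=float(row.x),
                    y=float(row.y),
                    intensity=float(row.intensity),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
    return out


def write_detections(detections: list[Detection], path) -> None:
    df = pd.DataFrame(
        [(d.channel, d.frame, d.x, d.y, d.intensity) for d in detections],
        columns=DETECTION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_trajectories(path) -> list[DonorAcceptorTrajectory]:
    """Read a trajectories CSV; rows are grouped by ``traj_id``.

    Within each trajectory, rows are sorted by frame; a duplicated
    (traj_id, frame) pair raises a :class:`ValidationError`.  Trajectory
    order follows first appearance in the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TRAJECTORY_COLUMNS, path)
    trajs: list[DonorAcceptorTrajectory] = []
    for traj_id, g in df.groupby("traj_id", sort=False):
        g = g.sort_values("frame", kind="stable")
        frames = g["frame"].to_numpy(dtype=np.int64)
        if len(np.unique(frames)) != len(frames):
            raise ValidationError(f"{path}: trajectory {traj_id}: duplicate frame")
        trajs.append(
            DonorAcceptorTrajectory(
                id=str(traj_id),
                cell_id=str(g["cell_id"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
                frames=frames,
                acceptor_xy=g[["acc_x", "acc_y"]].to_numpy(dtype=float),
                donor_xy=g[["don_x", "don_y"]].to_numpy(dtype=float),
                acceptor_intensity=g["acc_intensity"].to_numpy(dtype=float),
                donor_intensity=g["don_intensity"].to_numpy(dtype=float),
            )
        )
    return trajs


def write_trajectories(trajectories: list[DonorAcceptorTrajectory], path) -> None:
    frames_of = []
    for t in trajectories:
        n = len(t)
        frames_of.append(
            pd.DataFrame(
                {
                    "traj_id": np.repeat(t.id, n),
                    "cell_id": np.repeat(t.cell_id, n),
                    "condition": np.repeat(t.condition, n),
                    "frame": t.frames,
                    "acc_x": t.acceptor_xy[:, 0],
                    "acc_y": t.acceptor_xy[:, 1],
                    "don_x": t.donor_xy[:, 0],
                    "don_y": t.donor_xy[:, 1],
                    "acc_intensity": t.acceptor_intensity,
                    "don_intensity": t.donor_intensity,
                }
            )
        )
    if frames_of:
        df = pd.concat(frames_of, ignore_index=True)
    else:
        df = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    # full float precision so that read/write round-trips bit-exactly
    df.to_csv(path, index=False, float_format="%.17g")


def write_trajectories_hdf5(trajectories: list[DonorAcceptorTrajectory], path) -> None:
    with h5py.File(path, "w") as f:
        for i, t in enumerate(trajectories):
            g = f.create_group(f"traj_{i:06d}")
            g.attrs["id"] = t.id
            g.attrs["cell_id"] = t.cell_id
            g.attrs["condition"] = t.condition
            g.create_dataset("frames", data=t.frames)
            g.create_dataset("acceptor_xy", data=t.acceptor_xy)
            g.create_dataset("donor_xy", data=t.donor_xy)
            g.create_dataset("acceptor_intensity", data=t.acceptor_intensity)
            g.create_dataset("donor_intensity", data=t.donor_intensity)


def read_trajectories_hdf5(path) -> list[DonorAcceptorTrajectory]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                DonorAcceptorTrajectory(
                    id=str(g.attrs["id"]),
                    cell_id=str(g.attrs["cell_id"]),
                    condition=str(g.attrs["condition"]),
                    frames=g["frames"][()],
                    acceptor_xy=g["acceptor_xy"][()],
                    donor_xy=g["donor_xy"][()],
                    acceptor_intensity=g["acceptor_intensity"][()],
                    donor_intensity=g["donor_intensity"][()],
                )
            )
    return out


def filter_min_length(
    trajectories: list[DonorAcceptorTrajectory], min_frames: int = 20
) -> list[DonorAcceptorTrajectory]:
    """Keep trajectories with at least ``min_frames`` frames, order preserved.

    Motion-state analysis upstream requires at least 20 tracked frames, which
    is the default bound.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [t for t in trajectories if len(t) >= min_frames]


def apply_transform(points, transform) -> np.ndarray:
    """Apply a 2x3 affine map to an (n, 2) array of (x, y) points.

    ``transform`` rows are (a, b, tx) and (c, d, ty):
    x' = a*x + b*y + tx, y' = c*x + d*y + ty.  The identity transform
    returns the input values bit-exactly.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    m = np.asarray(transform, dtype=float)
    if m.shape != (2, 3):
        raise ValueError(f"transform must be 2x3, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValidationError("transform contains non-finite coefficients")
    if np.array_equal(m, IDENTITY_TRANSFORM):
        return pts.copy()
    return pts @ m[:, :2].T + m[:, 2]


IDENTITY_TRANSFORM = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
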