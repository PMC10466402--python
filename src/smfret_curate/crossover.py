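"""Frame-level crossing-over detection.

For the i-th donor–acceptor trajectory and each frame t, the per-channel
density rho_i(t) counts all detections in that channel lying strictly within
d_min pixels of the trajectory position.  At a frame where the trajectory's
own particle was re-detected the density is at least 1 (distance 0), so a
frame is free of crossing-over exactly when both densities are <= 1.  When
the donor is quenched at very high FRET it produces no donor detection and
rho_donor is 0; such frames are kept (0 <= 1).

The keep mask is the frame-inclusion condition used to stitch the surviving
frames of a trajectory into a curated FRET trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Detection, DonorAcceptorTrajectory


@dataclass
class CrossoverProfile:
    """Per-frame densities and the derived keep/drop mask for one trajectory."""

    traj_id: str
    frames: np.ndarray
    rho_acceptor: np.ndarray
    rho_donor: np.ndarray
    keep_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    @property
    def n_dropped(self) -> int:
        return len(self) - self.n_kept


@dataclass
class CrossoverSummary:
    """Bookkeeping counts over a set of crossing-over profiles."""

    n_trajectories: int
    n_frames_total: int
    n_frames_multi_donor: int
    n_frames_multi_acceptor: int
    n_traj_acceptor_multi_near_end: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class DetectionIndex:
    """Per-frame spatial index over the detections of one channel.

    Accepts a list of :class:`Detection` or a DataFrame with columns
    ``frame, x, y``.  KD-trees are built lazily per frame; radius queries
    use a strict ``< radius`` criterion (a detection at exactly the search
    radius is not counted).
    """

    def __init__(self, detections) -> None:
        if isinstance(detections, pd.DataFrame):
            frames = detections["frame"].to_numpy(dtype=np.int64)
            xy = detections[["x", "y"]].to_numpy(dtype=float)
        else:
            frames = np.array([d.frame for d in detections], dtype=np.int64)
            xy = np.array([[d.x, d.y] for d in detections], dtype=float).reshape(-1, 2)
        order = np.argsort(frames, kind="stable")
        frames = frames[order]
        xy = xy[order]
        self._positions: dict[int, np.ndarray] = {}
        if len(frames):
            uniq, starts = np.unique(frames, return_index=True)
            bounds = np.append(starts, len(frames))
            for f, a, b in zip(uniq, bounds[:-1], bounds[1:]):
                self._positions[int(f)] = xy[a:b]
        self._trees: dict[int, cKDTree] = {}

    def positions_at(self, frame: int) -> np.ndarray:
        return self._positions.get(int(frame), np.empty((0, 2)))

    def _tree(self, frame: int) -> cKDTree | None:
        frame = int(frame)
        if frame not in self._positions:
            return None
        if frame not in self._trees:
            self._trees[frame] = cKDTree(self._positions[frame])
        return self._trees[frame]

    def count_within(self, frame: int, point, radius: float) -> int:
        """Number of detections at ``frame`` strictly closer than ``radius``."""
        tree = self._tree(frame)
        if tree is None:
            return 0
        idx = tree.query_ball_point(np.asarray(point, dtype=float), radius)
        if not idx:
            return 0
        pts = self._positions[int(frame)][idx]
        d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
        return int(np.count_nonzero(d < radius))


def distances_at_frame(
    traj: DonorAcceptorTrajectory, t: int, index: DetectionIndex
) -> np.ndarray:
    """Euclidean distances from the trajectory position at frame ``t`` to
    every detection of the indexed channel at ``t`` (empty if none)."""
    where = np.flatnonzero(traj.frames == t)
    if len(where) == 0:
        raise IndexError(f"frame {t} not in trajectory {traj.id}")
    x, y = traj.acceptor_xy[where[0]]
    pts = index.positions_at(t)
    return np.hypot(pts[:, 0] - x, pts[:, 1] - y)


def density_profile(
    traj: DonorAcceptorTrajectory,
    acceptor_index: DetectionIndex,
    donor_index: DetectionIndex,
    d_min: float = 6.0,
) -> CrossoverProfile:
    """Per-frame detection densities around the trajectory and the keep mask.

    The search is centred on the acceptor position in both channels, since
    the donor ROI is mapped from the acceptor localisation.  A frame is kept
    when both channel densities are <= 1.
    """
    if not d_min > 0:
        raise ValueError("d_min must be positive")
    n = len(traj)
    rho_a = np.zeros(n, dtype=np.int64)
    rho_d = np.zeros(n, dtype=np.int64)
    for k in range(n):
        p = traj.acceptor_xy[k]
        f = int(traj.frames[k])
        rho_a[k] = acceptor_index.count_within(f, p, d_min)
        rho_d[k] = donor_index.count_within(f, p, d_min)
    keep = (rho_a <= 1) & (rho_d <= 1)
    return CrossoverProfile(
        traj_id=traj.id, frames=traj.frames.copy(), rho_acceptor=rho_a,
        rho_donor=rho_d, keep_mask=keep,
    )


def stitch_kept_frames(
    traj: DonorAcceptorTrajectory, profile: CrossoverProfile
) -> tuple[DonorAcceptorTrajectory, list[tuple[int, int]]]:
    """Restrict a trajectory to its kept frames.

    Returns the restricted trajectory together with the contiguous kept
    segments as (start, stop) index pairs into the original arrays
    (half-open).  Kept plus dropped frame counts always sum to the original
    length.
    """
    if len(profile) != len(traj) or not np.array_equal(profile.frames, traj.frames):
        raise ValueError("profile does not match trajectory frames")
    mask = profile.keep_mask
    kept = DonorAcceptorTrajectory(
        id=traj.id,
        cell_id=traj.cell_id,
        condition=traj.condition,
        frames=traj.frames[mask],
        acceptor_xy=traj.acceptor_xy[mask],
        donor_xy=traj.donor_xy[mask],
        acceptor_intensity=traj.acceptor_intensity[mask],
        donor_intensity=traj.donor_intensity[mask],
    )
    segments: list[tuple[int, int]] = []
    start = None
    for k, keep in enumerate(mask):
        if keep and start is None:
            start = k
        elif not keep and start is not None:
            segments.append((start, k))
            start = None
    if start is not None:
        segments.append((start, len(mask)))
    return kept, segments


def summarize_crossovers(
    profiles: list[CrossoverProfile], end_window: int = 5
) -> CrossoverSummary:
    """Tabulate crossing-over counts over a trajectory set.

    ``n_traj_acceptor_multi_near_end`` counts trajectories where the
    acceptor-channel density exceeded 1 within the last ``end_window``
    frames — the signature of a crossing that may have terminated tracking.
    """
    if end_window < 1:
        raise ValueError("end_window must be >= 1")
    n_frames = sum(len(p) for p in profiles)
    n_multi_d = sum(int(np.count_nonzero(p.rho_donor > 1)) for p in profiles)
    n_multi_a = sum(int(np.count_nonzero(p.rho_acceptor > 1)) for p in profiles)
    n_end = sum(
        1 for p in profiles if np.any(p.rho_acceptor[-end_window:] > 1)
    )
    return CrossoverSummary(
        n_trajectories=len(profiles),
        n_frames_total=n_frames,
        n_frames_multi_donor=n_multi_d,
        n_frames_multi_acceptor=n_multi_a,
        n_traj_acceptor_multi_near_end=n_end,
    )


def profiles_to_frame(profiles: list[CrossoverProfile]) -> pd.DataFrame:
    """Long-format table ``traj_id,frame,rho_acc,rho_don,keep``."""
    parts = [
        pd.DataFrame(
            {
                "traj_id": np.repeat(p.traj_id, len(p)),
                "frame": p.frames,
                "rho_acc": p.rho_acceptor,
                "rho_don": p.rho_donor,
                "keep": p.keep_mask.astype(int),
            }
        )
        for p in profiles
    ]
    if parts:
        return pd.concat(parts, ignore_index=True)
    return pd.DataFrame(columns=["traj_id", "frame", "rho_acc", "rho_don", "keep"])


def profiles_from_frame(df: pd.DataFrame) -> list[CrossoverProfile]:
    out = []
    for traj_id, g in df.groupby("traj_id", sort=False):
        out.append(
            CrossoverProfile(
                traj_id=str(traj_id),
                frames=g["frame"].to_numpy(dtype=np.int64),
                rho_acceptor=g["rho_acc"].to_numpy(dtype=np.int64),
                rho_donor=g["rho_don"].to_numpy(dtype=np.int64),
                keep_mask=g["keep"].to_numpy() > 0,
            )
        )
    return out
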