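"""Corrected FRET efficiency traces and adjusted mean intensities.

The per-frame efficiency with corrections alpha (bleed-through), delta
(direct excitation) and gamma (detection efficiency/quantum yield ratio) is

    E = (Ia - alpha*Id - delta*It) / (gamma*Id + Ia - alpha*Id - delta*It)

with the total intensity It = Ia + Id (raw ROI sums).  Frames with a zero
denominator, or with invalid (NaN) intensities, are excluded rather than
set to zero — a fabricated value would create a spurious state.  Corrected
efficiencies are deliberately not clipped to [0, 1]; clipping would distort
the Gaussian state fits downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crossover import CrossoverProfile
from .model import CorrectionFactors, DonorAcceptorTrajectory


@dataclass
class FretTrace:
    """Per-frame FRET efficiencies over the kept frames of one trajectory."""

    traj_id: str
    frames: np.ndarray
    efficiency: np.ndarray
    cell_id: str = ""
    condition: str = ""

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class IntensitySummary:
    """Adjusted mean ROI intensities of one trajectory (crossover frames removed)."""

    traj_id: str
    mean_donor: float
    mean_acceptor: float
    n_kept: int
    cell_id: str = ""
    condition: str = ""

    @property
    def total(self) -> float:
        return self.mean_donor + self.mean_acceptor


def fret_efficiency(i_acceptor, i_donor, corr: CorrectionFactors):
    """Corrected FRET efficiency for scalar or array intensities.

    Returns ``NaN`` where the denominator vanishes (undefined frames).
    With alpha = delta = 0 and gamma = 1 this reduces to Ia / (Ia + Id).
    """
    ia = np.asarray(i_acceptor, dtype=float)
    id_ = np.asarray(i_donor, dtype=float)
    total = ia + id_
    numer = ia - corr.alpha * id_ - corr.delta * total
    denom = corr.gamma * id_ + numer
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom != 0, numer / np.where(denom != 0, denom, 1.0), np.nan)
    if np.ndim(i_acceptor) == 0 and np.ndim(i_donor) == 0:
        return float(e)
    return e


def fret_trace(
    traj: DonorAcceptorTrajectory,
    profile: CrossoverProfile,
    corr: CorrectionFactors,
) -> FretTrace:
    """Efficiency evaluated at kept frames only; undefined frames omitted."""
    if len(profile) != len(traj) or not np.array_equal(profile.frames, traj.frames):
        raise ValueError("profile does not match trajectory frames")
    mask = profile.keep_mask.copy()
    mask &= np.isfinite(traj.acceptor_intensity) & np.isfinite(traj.donor_intensity)
    e = fret_efficiency(traj.acceptor_intensity[mask], traj.donor_intensity[mask], corr)
    e = np.atleast_1d(e)
    defined = np.isfinite(e)
    return FretTrace(
        traj_id=traj.id,
        frames=traj.frames[mask][defined],
        efficiency=e[defined],
        cell_id=traj.cell_id,
        condition=traj.condition,
    )


def adjusted_mean_intensity(
    traj: DonorAcceptorTrajectory, profile: CrossoverProfile
) -> IntensitySummary | None:
    """Mean donor/acceptor ROI intensity over kept frames.

    Returns ``None`` when no kept frame has valid intensities; such a
    trajectory is excluded from the intensity-space representation.
    """
    if len(profile) != len(traj) or not np.array_equal(profile.frames, traj.frames):
        raise ValueError("profile does not match trajectory frames")
    mask = profile.keep_mask.copy()
    mask &= np.isfinite(traj.acceptor_intensity) & np.isfinite(traj.donor_intensity)
    n_kept = int(mask.sum())
    if n_kept == 0:
        return None
    return IntensitySummary(
        traj_id=traj.id,
        mean_donor=float(traj.donor_intensity[mask].mean()),
        mean_acceptor=float(traj.acceptor_intensity[mask].mean()),
        n_kept=n_kept,
        cell_id=traj.cell_id,
        condition=traj.condition,
    )
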