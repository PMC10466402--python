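"""Core data types for donor–acceptor trajectory curation.

Conventions used throughout the package:

* coordinates are in pixel units, the centre of pixel (0, 0) is (0.0, 0.0);
* frames are 0-based integers;
* intensities are ROI photon-count sums in arbitrary (camera) units.

A :class:`DonorAcceptorTrajectory` is the unit of curation: an acceptor-channel
track together with per-frame donor/acceptor ROI intensity traces.  Frames
whose ROI could not be evaluated carry ``NaN`` intensities and are ignored by
every downstream average and FRET computation — intensities are never
fabricated for missing frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DONOR = "donor"
ACCEPTOR = "acceptor"
CHANNELS = (DONOR, ACCEPTOR)


class ValidationError(ValueError):
    """A value violates a data-model invariant."""


class FormatError(ValueError):
    """An input file does not match the documented layout."""


@dataclass(frozen=True)
class Detection:
    """One localized fluorescent signal in one channel at one frame."""

    channel: str
    frame: int
    x: float
    y: float
    intensity: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.frame < 0:
            raise ValidationError(f"negative frame {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"non-finite coordinate ({self.x}, {self.y}) at frame {self.frame}"
            )
        if not math.isfinite(self.intensity):
            raise ValidationError(f"non-finite intensity at frame {self.frame}")


@dataclass
class Track:
    """An upstream tracker output: ordered detections in one channel."""

    id: str
    channel: str
    detections: list[Detection]

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError(f"track {self.id}: frames not strictly increasing")
        if any(d.channel != self.channel for d in self.detections):
            raise ValidationError(f"track {self.id}: mixed channels")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions."""
        return np.array([[d.x, d.y] for d in self.detections], dtype=float).reshape(-1, 2)


@dataclass
class DonorAcceptorTrajectory:
    """An acceptor track with per-frame donor/acceptor ROI intensities.

    ``donor_xy`` holds the donor-channel positions mapped from the acceptor
    localisations; after channel registration they coincide with
    ``acceptor_xy``.  The 20-frame minimum-length requirement is enforced by
    :func:`smfret_curate.io.filter_min_length`, not by the constructor, so
    that raw tracker output can be represented before filtering.
    """

    id: str
    cell_id: str
    condition: str
    frames: np.ndarray
    acceptor_xy: np.ndarray
    donor_xy: np.ndarray
    acceptor_intensity: np.ndarray
    donor_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.acceptor_xy = np.asarray(self.acceptor_xy, dtype=float).reshape(-1, 2)
        self.donor_xy = np.asarray(self.donor_xy, dtype=float).reshape(-1, 2)
        self.acceptor_intensity = np.asarray(self.acceptor_intensity, dtype=float)
        self.donor_intensity = np.asarray(self.donor_intensity, dtype=float)
        n = len(self.frames)
        for name in ("acceptor_xy", "donor_xy", "acceptor_intensity", "donor_intensity"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"trajectory {self.id}: {name} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if n and np.any(np.diff(self.frames) <= 0):
            raise ValidationError(f"trajectory {self.id}: frames not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class CorrectionFactors:
    """FRET correction factors.

    alpha
        donor→acceptor spectral bleed-through fraction.
    delta
        acceptor direct-excitation fraction at the donor excitation
        wavelength.
    gamma
        relative detection-efficiency / quantum-yield ratio of the two
        fluorophores.

    The identity (alpha = delta = 0, gamma = 1) reduces the corrected
    efficiency to the uncorrected ratio Ia / (Ia + Id).
    """

    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValidationError("gamma must be positive")
        if self.alpha < 0 or self.delta < 0:
            raise ValidationError("alpha and delta must be non-negative")
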