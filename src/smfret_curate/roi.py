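"""ROI intensity extraction from two-channel image stacks.

Intensities are the raw sum of pixel values inside a square window
(default 5x5 pixels) centred on the nearest-integer pixel of the particle
position.  Windows that would cross the image border yield ``NaN`` (the
frame is marked invalid) instead of a padded or clipped sum, which would
bias intensity downward asymmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .model import DonorAcceptorTrajectory, Track, ValidationError
from .io import IDENTITY_TRANSFORM, apply_transform

INVALID = float("nan")


@dataclass
class ImageStack:
    """A (t, row, col) stack of non-negative intensities for one channel."""

    frames: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("image stack must be a non-empty (t, row, col) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def round_half_away(v: float) -> int:
    """Round to nearest integer, halves away from zero (unlike banker's)."""
    return int(np.sign(v) * np.floor(abs(v) + 0.5))


def roi_sum(
    stack: ImageStack,
    frame: int,
    center: tuple[float, float],
    half_width: int = 2,
    background: float = 0.0,
) -> float:
    """Sum pixel values in a (2*half_width+1)^2 window around ``center``.

    ``center`` is (x, y) in pixel units; x indexes columns, y rows.  A
    constant per-pixel ``background`` offset may be subtracted (default 0:
    raw sums).  Returns ``NaN`` when the window exceeds the image bounds.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if not 0 <= frame < stack.n_frames:
        raise IndexError(f"frame {frame} outside stack of {stack.n_frames} frames")
    x, y = center
    col = round_half_away(x)
    row = round_half_away(y)
    n_rows, n_cols = stack.frames.shape[1:]
    if (
        row - half_width < 0
        or col - half_width < 0
        or row + half_width >= n_rows
        or col + half_width >= n_cols
    ):
        return INVALID
    window = stack.frames[
        frame, row - half_width : row + half_width + 1, col - half_width : col + half_width + 1
    ]
    total = float(window.sum())
    return total - background * (2 * half_width + 1) ** 2


def extract_traces(
    stack_donor: ImageStack,
    stack_acceptor: ImageStack,
    acceptor_track: Track,
    transform=IDENTITY_TRANSFORM,
    half_width: int = 2,
    cell_id: str = "cell0",
    condition: str = "",
    background: float = 0.0,
) -> DonorAcceptorTrajectory:
    """Build a donor–acceptor trajectory from raw stacks and an acceptor track.

    The acceptor ROI is centred on each tracked acceptor position; the donor
    ROI is centred on the same position mapped into the donor channel by the
    affine ``transform`` (identity when channels are pre-registered).
    Frames with out-of-bounds windows carry ``NaN`` intensities.
    """
    if len(acceptor_track) == 0:
        raise ValidationError("empty acceptor track")
    frames = acceptor_track.frames
    acc_xy = acceptor_track.positions
    don_xy = apply_transform(acc_xy, transform)
    acc_int = np.array(
        [
            roi_sum(stack_acceptor, int(f), (x, y), half_width, background)
            for f, (x, y) in zip(frames, acc_xy)
        ]
    )
    don_int = np.array(
        [
            roi_sum(stack_donor, int(f), (x, y), half_width, background)
            for f, (x, y) in zip(frames, don_xy)
        ]
    )
    return DonorAcceptorTrajectory(
        id=acceptor_track.id,
        cell_id=cell_id,
        condition=condition,
        frames=frames,
        acceptor_xy=acc_xy,
        donor_xy=don_xy,
        acceptor_intensity=acc_int,
        donor_intensity=don_int,
    )


def read_stack(path, channel: str) -> ImageStack:
    """Read a multi-page TIFF as an image stack; page index = frame index."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(frames=data, channel=channel)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
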