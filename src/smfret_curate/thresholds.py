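"""Bleach-anchored template selection and intensity thresholding.

A genuine FRET pair reveals itself when its acceptor photobleaches in a
single step: the acceptor intensity drops to the background while the donor,
released from energy transfer, rises to its intrinsic intensity.  This
anti-correlated step is quantified with an auROC statistic comparing an
intensity window before the bleach against a window after it: values near 0
mean a drop, near 1 a rise, near 0.5 no step.

Crossover-free trajectories whose acceptor auROC is close to 0 and donor
auROC close to 1 serve as *templates*; the intensity thresholds

* ``donor_max``   — the maximum donor intensity attained in any template's
  post-bleach window (the intrinsic donor ceiling),
* ``acceptor_min`` — the smallest adjusted mean acceptor intensity among
  templates (the floor for resolving an acceptor above noise),
* ``total_max``   = donor_max + acceptor_min,

bound the region of intensity space where a single donor–acceptor pair is
physically plausible.  Trajectories inside that region are partitioned into
high / medium / low FRET wedges by the uncorrected ratio
r = Ia / (Ia + Id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crossover import CrossoverProfile
from .fret import IntensitySummary
from .model import DonorAcceptorTrajectory, ValidationError

HIGH = "high"
MEDIUM = "medium"
LOW = "low"
REJECTED = "rejected"
REGION_LABELS = (HIGH, MEDIUM, LOW, REJECTED)


class TemplateSelectionError(RuntimeError):
    """No template trajectory satisfied the selection criteria."""


@dataclass(frozen=True)
class BleachEvent:
    """A detected single-step acceptor bleach within one trajectory.

    ``t_bleach`` is the positional index (into the trajectory arrays) of the
    first frame at the post-bleach level.
    """

    traj_id: str
    t_bleach: int
    auroc_acceptor: float
    auroc_donor: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc_acceptor <= 1.0 and 0.0 <= self.auroc_donor <= 1.0):
            raise ValidationError("auROC values must lie in [0, 1]")


@dataclass(frozen=True)
class Thresholds:
    """Intensity-space acceptance boundaries inferred from templates."""

    acceptor_min: float
    donor_max: float

    @property
    def total_max(self) -> float:
        return self.donor_max + self.acceptor_min

    def __post_init__(self) -> None:
        if not self.acceptor_min > 0:
            raise ValidationError("acceptor_min must be positive")

    def to_dict(self) -> dict:
        return {
            "acceptor_min": self.acceptor_min,
            "donor_max": self.donor_max,
            "total_max": self.total_max,
        }


def detect_bleach_frame(
    acceptor_intensity, noise_floor: float, confirm_window: int = 5
) -> int | None:
    """Locate a single-step, persistent acceptor bleach.

    Returns the positional index of the largest downward step that lands at
    the bleached level: both the median of the ``confirm_window`` frames
    immediately after the step and the median of the whole remaining trace
    must lie below ``noise_floor``, while the median before the step sits at
    or above it.  Returns ``None`` when no step qualifies.  A transient drop
    followed by recovery (blinking) fails the whole-remainder condition; a
    large FRET state transition that leaves the acceptor above the floor
    fails the immediate-window condition.
    """
    x = np.asarray(acceptor_intensity, dtype=float)
    n = len(x)
    if n < 3:
        return None
    best: int | None = None
    best_drop = 0.0
    for t in range(1, n):
        drop = x[t - 1] - x[t]
        if drop <= 0:
            continue
        if np.median(x[t : t + confirm_window]) >= noise_floor:
            continue
        if np.median(x[t:]) >= noise_floor:
            continue
        if np.median(x[:t]) < noise_floor:
            continue
        if drop > best_drop:
            best_drop = drop
            best = t
    return best


def estimate_noise_floor(acceptor_intensity, k: float = 3.0) -> float:
    """Robust noise floor: k times the frame-to-frame scatter of the trace.

    The scatter is estimated from first differences (median absolute
    deviation scaled to a Gaussian sigma, divided by sqrt(2)), which is
    insensitive to the bleach step itself.
    """
    x = np.asarray(acceptor_intensity, dtype=float)
    d = np.diff(x[np.isfinite(x)])
    if len(d) == 0:
        return 0.0
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    return k * sigma


def auroc(trace, t_bleach: int, w_pre: int, w_post: int) -> float | None:
    """Area under the ROC comparing post- vs pre-bleach intensity windows.

    Equals P(post > pre) + 0.5 P(post = pre) over all window pairs
    (Mann–Whitney U divided by w_pre*w_post).  The transition frame
    ``t_bleach`` itself is excluded from both windows.  Returns ``None``
    when either window does not fit inside the trace.
    """
    if w_pre < 1 or w_post < 1:
        raise ValueError("window lengths must be >= 1")
    x = np.asarray(trace, dtype=float)
    if t_bleach - w_pre < 0 or t_bleach + 1 + w_post > len(x):
        return None
    pre = x[t_bleach - w_pre : t_bleach]
    post = x[t_bleach + 1 : t_bleach + 1 + w_post]
    diff = post[:, None] - pre[None, :]
    u = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(u) / (w_pre * w_post)


def compute_bleach_events(
    trajectories: list[DonorAcceptorTrajectory],
    noise_floor: float | None = None,
    w_pre: int = 10,
    w_post: int = 10,
) -> dict[str, BleachEvent]:
    """Detect acceptor bleaches and score both channels' auROC per trajectory.

    ``noise_floor=None`` uses a per-trace robust estimate
    (:func:`estimate_noise_floor`).  Trajectories without a detected bleach,
    or whose bleach sits too close to either end for the auROC windows, are
    omitted from the result.
    """
    events: dict[str, BleachEvent] = {}
    for traj in trajectories:
        floor = noise_floor
        if floor is None:
            floor = estimate_noise_floor(traj.acceptor_intensity)
        t_b = detect_bleach_frame(traj.acceptor_intensity, floor)
        if t_b is None:
            continue
        a_acc = auroc(traj.acceptor_intensity, t_b, w_pre, w_post)
        a_don = auroc(traj.donor_intensity, t_b, w_pre, w_post)
        if a_acc is None or a_don is None:
            continue
        events[traj.id] = BleachEvent(
            traj_id=traj.id, t_bleach=t_b, auroc_acceptor=a_acc, auroc_donor=a_don
        )
    return events


def select_templates(
    trajectories: list[DonorAcceptorTrajectory],
    profiles: dict[str, CrossoverProfile],
    bleach_events: dict[str, BleachEvent],
    auroc_acceptor_max: float = 0.2,
    auroc_donor_min: float = 0.8,
) -> set[str]:
    """Template trajectories: crossover-free with anti-correlated bleaching.

    A template must (a) have an all-true keep mask, (b) carry a detected
    bleach event, (c) have acceptor auROC <= ``auroc_acceptor_max`` and
    (d) donor auROC >= ``auroc_donor_min``.  Correlated co-bleachers (donor
    drops with the acceptor) fail criterion (d).
    """
    if not (0.0 <= auroc_acceptor_max <= 1.0 and 0.0 <= auroc_donor_min <= 1.0):
        raise ValueError("auROC cutoffs must lie in [0, 1]")
    templates: set[str] = set()
    for traj in trajectories:
        ev = bleach_events.get(traj.id)
        if ev is None:
            continue
        prof = profiles.get(traj.id)
        if prof is None or not bool(prof.keep_mask.all()):
            continue
        if ev.auroc_acceptor <= auroc_acceptor_max and ev.auroc_donor >= auroc_donor_min:
            templates.add(traj.id)
    if not templates:
        raise TemplateSelectionError(
            "no template trajectories found; relax the auROC cutoffs "
            "(auroc.acceptor_max / auroc.donor_min) or provide more data — "
            "thresholds cannot be inferred from an empty template set"
        )
    return templates


def infer_thresholds(
    templates: set[str],
    trajectories: list[DonorAcceptorTrajectory],
    bleach_events: dict[str, BleachEvent],
    w_post: int = 10,
    profiles: dict[str, CrossoverProfile] | None = None,
) -> Thresholds:
    """Intensity thresholds from the template set.

    ``donor_max`` is the maximum per-frame donor intensity in the w_post
    frames following each template's bleach; ``acceptor_min`` the minimum
    over templates of the mean acceptor intensity across pre-bleach kept
    frames.
    """
    if not templates:
        raise TemplateSelectionError("cannot infer thresholds from an empty template set")
    by_id = {t.id: t for t in trajectories}
    donor_max = -np.inf
    acceptor_min = np.inf
    for tid in sorted(templates):
        traj = by_id[tid]
        ev = bleach_events[tid]
        b = ev.t_bleach
        post = traj.donor_intensity[b + 1 : b + 1 + w_post]
        pre_mask = np.zeros(len(traj), dtype=bool)
        pre_mask[:b] = True
        if profiles is not None and tid in profiles:
            pre_mask &= profiles[tid].keep_mask
        pre_mask &= np.isfinite(traj.acceptor_intensity)
        if len(post) == 0 or not pre_mask.any():
            continue
        donor_max = max(donor_max, float(np.nanmax(post)))
        acceptor_min = min(acceptor_min, float(traj.acceptor_intensity[pre_mask].mean()))
    if not np.isfinite(donor_max) or not np.isfinite(acceptor_min):
        raise TemplateSelectionError("no template had usable pre/post-bleach windows")
    return Thresholds(acceptor_min=acceptor_min, donor_max=donor_max)


def classify_region(
    summary: IntensitySummary,
    th: Thresholds,
    bounds: tuple[float, float] = (0.3, 0.7),
) -> str:
    """Assign an intensity summary to a FRET region of intensity space.

    With r = mean_acc / (mean_acc + mean_don): rejected when the acceptor
    mean is at or below ``acceptor_min`` or the total at or above
    ``total_max`` (strict interior acceptance); otherwise high if r > 0.7,
    medium if 0.3 < r <= 0.7, low if r <= 0.3.  The partition over the
    accepted wedge is exhaustive and exclusive.
    """
    low_b, high_b = bounds
    acc = summary.mean_acceptor
    don = summary.mean_donor
    if acc <= th.acceptor_min or acc + don >= th.total_max:
        return REJECTED
    r = acc / (acc + don)
    if r > high_b:
        return HIGH
    if r > low_b:
        return MEDIUM
    return LOW
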