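"""Synthetic two-channel smFRET scenes with a complete ground-truth ledger.

The generator emulates the statistical structure the curation pipeline
assumes:

* sensitized-acceptor FRET pairs diffusing by 2-D Brownian motion in a
  bounded field (reflecting boundaries), tracked in the acceptor channel;
* far more donor-channel than acceptor-channel detections (M >> N), because
  donor-only particles (directly excited) populate the donor channel at a
  configurable density while only FRET pairs appear in the acceptor channel;
* multi-state FRET dynamics: a discrete-state Markov chain per pair whose
  state means partition a constant pair intensity between the two channels
  (anti-correlated donor/acceptor by construction);
* occasional single-step acceptor photobleaching with donor recovery to its
  intrinsic intensity, and quenched-donor frames (no donor detection) when
  the donor intensity falls below the detection floor at high FRET;
* per-frame track-loss hazard exceeding the bleach hazard by default, so
  tracking is typically lost before photobleaching.

Detection tables are emitted noiselessly from the true positions by default
(``localization_error_sd = 0``) so that crossing-over ground truth is exact.
The ledger records, per trajectory, the planted state sequence, the frames
at which any channel's detection density around the pair exceeds one, the
bleach frame, and the noise-free intensities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ACCEPTOR, DONOR, DonorAcceptorTrajectory, ValidationError
from . import io as _io


@dataclass
class SceneParams:
    """Parameters of a synthetic scene.

    Defaults mirror a typical live-cell acquisition: 4,000 frames at 25 Hz,
    a mean track lifetime of ~100 frames (loss hazard 0.01/frame) well below
    the bleach lifetime (hazard 0.001/frame), pair intensity 1,000 counts
    with 50-count frame noise, and three FRET states centred at
    0.25 / 0.50 / 0.80.
    """

    field_size: tuple[int, int] = (128, 128)
    n_frames: int = 4000
    frame_rate_hz: float = 25.0  # metadata only
    n_fret_pairs: int = 30
    donor_only_density: float = 8.0  # particles per 100x100 px
    diffusion_coefficient: float = 0.05  # px^2 / frame
    fret_state_means: tuple[float, ...] = (0.25, 0.50, 0.80)
    fret_state_sds: tuple[float, ...] = (0.02, 0.02, 0.02)
    state_stay_prob: float = 0.98
    state_transition_probs: np.ndarray | None = None  # rows sum to 1
    donor_intrinsic_intensity: float = 1000.0
    intensity_noise_sd: float = 50.0
    acceptor_bleach_prob_per_frame: float = 0.001
    track_loss_prob_per_frame: float = 0.01
    track_lifetime_fret_coupling: float = 0.0  # >0: high-FRET tracks live longer
    background_rate: float = 0.0
    donor_detection_min: float = 120.0  # intrinsic donor floor for a detection
    n_spurious_acceptor_tracks: int = 0
    spurious_intensity: float = 80.0
    spurious_mean_lifetime: float = 30.0
    localization_error_sd: float = 0.0
    d_min_px: float = 6.0  # radius used for the ground-truth crossing ledger
    seed: int = 0

    def transition_matrix(self) -> np.ndarray:
        k = len(self.fret_state_means)
        if self.state_transition_probs is not None:
            m = np.asarray(self.state_transition_probs, dtype=float)
            if m.shape != (k, k) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValidationError("transition matrix rows must sum to 1")
            return m
        if k == 1:
            return np.ones((1, 1))
        off = (1.0 - self.state_stay_prob) / (k - 1)
        m = np.full((k, k), off)
        np.fill_diagonal(m, self.state_stay_prob)
        return m

    def validate(self) -> None:
        if self.n_frames < 1 or self.n_fret_pairs < 0:
            raise ValidationError("n_frames must be >= 1 and n_fret_pairs >= 0")
        if self.donor_only_density < 0 or self.diffusion_coefficient < 0:
            raise ValidationError("densities and diffusion must be non-negative")
        if len(self.fret_state_means) != len(self.fret_state_sds):
            raise ValidationError("state means and sds must have equal length")
        if not 0 <= self.track_lifetime_fret_coupling < 1:
            raise ValidationError("track_lifetime_fret_coupling must be in [0, 1)")
        self.transition_matrix()


@dataclass
class TrajectoryTruth:
    """Ground truth for one simulated trajectory (a test oracle)."""

    kind: str  # pair | spurious | template | correlated
    states: np.ndarray  # state index per frame (-1 for spurious)
    efficiency: np.ndarray  # planted E per frame (NaN for spurious)
    bleach_index: int | None  # positional index of first bleached frame
    crossing_frames_acceptor: np.ndarray  # absolute frame numbers, density > 1
    crossing_frames_donor: np.ndarray
    intrinsic_donor: np.ndarray
    intrinsic_acceptor: np.ndarray


@dataclass
class GroundTruth:
    per_trajectory: dict[str, TrajectoryTruth] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for tid, t in self.per_trajectory.items():
            out[tid] = {
                "kind": t.kind,
                "states": t.states.tolist(),
                "efficiency": t.efficiency.tolist(),
                "bleach_index": t.bleach_index,
                "crossing_frames_acceptor": t.crossing_frames_acceptor.tolist(),
                "crossing_frames_donor": t.crossing_frames_donor.tolist(),
            }
        return out


@dataclass
class Scene:
    params: SceneParams
    donor_detections: pd.DataFrame  # columns: frame, x, y, intensity, particle
    acceptor_detections: pd.DataFrame
    trajectories: list[DonorAcceptorTrajectory]
    truth: GroundTruth

    def detections(self, channel: str) -> pd.DataFrame:
        return self.donor_detections if channel == DONOR else self.acceptor_detections

    def write(self, out_dir) -> None:
        """Write detections/trajectories CSVs and the ground-truth ledger."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for ch, df in ((DONOR, self.donor_detections), (ACCEPTOR, self.acceptor_detections)):
            if len(df) == 0:
                continue
            d = df[["frame", "x", "y", "intensity"]].copy()
            d.insert(0, "channel", ch)
            rows.append(d)
        if rows:
            dets = pd.concat(rows, ignore_index=True)
        else:
            dets = pd.DataFrame(columns=["channel", "frame", "x", "y", "intensity"])
        dets.to_csv(out / "detections.csv", index=False, float_format="%.17g")
        _io.write_trajectories(self.trajectories, out / "trajectories.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(self.truth.to_dict(), indent=1, sort_keys=True)
        )


def _reflect(p: np.ndarray, size: float) -> np.ndarray:
    """Fold coordinates into [0, size] as a reflecting boundary."""
    m = np.mod(p, 2 * size)
    return np.where(m > size, 2 * size - m, m)


def _random_walk(rng, start, n: int, d_coef: float, field_size) -> np.ndarray:
    w, h = field_size
    steps = rng.normal(0.0, math.sqrt(2.0 * d_coef), size=(n, 2))
    steps[0] = 0.0
    pos = np.asarray(start, dtype=float) + np.cumsum(steps, axis=0)
    pos[:, 0] = _reflect(pos[:, 0], w)
    pos[:, 1] = _reflect(pos[:, 1], h)
    return pos


def _markov_states(rng, trans: np.ndarray, n: int) -> np.ndarray:
    k = trans.shape[0]
    s = np.empty(n, dtype=np.int64)
    s[0] = rng.integers(k)
    for t in range(1, n):
        s[t] = rng.choice(k, p=trans[s[t - 1]])
    return s


def _pair_lifetime(rng, params: SceneParams, states, n_max: int) -> int:
    """Frames survived before track loss; hazard can shrink with FRET level."""
    means = np.asarray(params.fret_state_means)
    for t in range(1, n_max):
        hazard = params.track_loss_prob_per_frame * (
            1.0 - params.track_lifetime_fret_coupling * means[states[t - 1]]
        )
        if rng.random() < hazard:
            return t
    return n_max


class _SceneBuilder:
    def __init__(self, params: SceneParams):
        params.validate()
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.det_rows: dict[str, list] = {DONOR: [], ACCEPTOR: []}
        self.trajs: list[DonorAcceptorTrajectory] = []
        self.truth = GroundTruth()

    # -- particle factories -------------------------------------------------

    def add_pair(
        self,
        traj_id: str,
        birth: int,
        n_live: int,
        start_xy,
        bleach_index: int | None,
        kind: str = "pair",
        cell_id: str = "cell0",
        condition: str = "synthetic",
        states: np.ndarray | None = None,
    ) -> None:
        """One donor–acceptor pair: states, intensities, detections, trajectory.

        ``bleach_index`` is positional; ``kind='correlated'`` makes the donor
        drop together with the acceptor at the bleach (a co-bleacher, not a
        FRET signature).  ``states`` may carry a pre-drawn state path (used
        when the track-loss hazard was evaluated against that same path).
        """
        p, rng = self.params, self.rng
        pos = _random_walk(rng, start_xy, n_live, p.diffusion_coefficient, p.field_size)
        if states is None:
            states = _markov_states(rng, p.transition_matrix(), n_live)
        else:
            states = np.asarray(states[:n_live], dtype=np.int64).copy()
        means = np.asarray(p.fret_state_means)
        sds = np.asarray(p.fret_state_sds)
        eff = np.clip(means[states] + rng.normal(0.0, 1.0, n_live) * sds[states], 0.0, 1.0)
        i0 = p.donor_intrinsic_intensity
        ia_int = eff * i0
        id_int = (1.0 - eff) * i0
        if bleach_index is not None:
            ia_int[bleach_index:] = 0.0
            if kind == "correlated":
                id_int[bleach_index:] = 0.0
            else:
                id_int[bleach_index:] = i0
            eff[bleach_index:] = np.nan
            states[bleach_index:] = -1
        noise = p.intensity_noise_sd
        ia_meas = ia_int + p.background_rate + rng.normal(0.0, noise, n_live)
        id_meas = id_int + p.background_rate + rng.normal(0.0, noise, n_live)
        frames = birth + np.arange(n_live)
        loc = p.localization_error_sd
        for t in range(n_live):
            jitter = rng.normal(0.0, loc, 2) if loc > 0 else np.zeros(2)
            if bleach_index is None or t < bleach_index:
                self.det_rows[ACCEPTOR].append(
                    (frames[t], pos[t, 0] + jitter[0], pos[t, 1] + jitter[1],
                     ia_meas[t], traj_id)
                )
            if id_int[t] >= p.donor_detection_min:
                self.det_rows[DONOR].append(
                    (frames[t], pos[t, 0] + jitter[0], pos[t, 1] + jitter[1],
                     id_meas[t], traj_id)
                )
        self.trajs.append(
            DonorAcceptorTrajectory(
                id=traj_id, cell_id=cell_id, condition=condition,
                frames=frames, acceptor_xy=pos, donor_xy=pos.copy(),
                acceptor_intensity=ia_meas, donor_intensity=id_meas,
            )
        )
        self.truth.per_trajectory[traj_id] = TrajectoryTruth(
            kind=kind, states=states, efficiency=eff, bleach_index=bleach_index,
            crossing_frames_acceptor=np.empty(0, dtype=np.int64),
            crossing_frames_donor=np.empty(0, dtype=np.int64),
            intrinsic_donor=id_int, intrinsic_acceptor=ia_int,
        )

    def add_donor_only(self, particle_id: str) -> None:
        """A directly excited donor-channel particle, alive the whole movie."""
        p, rng = self.params, self.rng
        w, h = p.field_size
        start = rng.uniform((0, 0), (w, h))
        pos = _random_walk(rng, start, p.n_frames, p.diffusion_coefficient, p.field_size)
        inten = rng.normal(p.donor_intrinsic_intensity, p.intensity_noise_sd, p.n_frames)
        loc = p.localization_error_sd
        jit = rng.normal(0.0, loc, (p.n_frames, 2)) if loc > 0 else np.zeros((p.n_frames, 2))
        for t in range(p.n_frames):
            self.det_rows[DONOR].append(
                (t, pos[t, 0] + jit[t, 0], pos[t, 1] + jit[t, 1], inten[t], particle_id)
            )

    def add_spurious_acceptor(self, traj_id: str, cell_id: str = "cell0",
                              condition: str = "synthetic") -> None:
        """A short, dim acceptor-channel track with no donor partner."""
        p, rng = self.params, self.rng
        w, h = p.field_size
        n_live = min(int(rng.geometric(1.0 / p.spurious_mean_lifetime)), p.n_frames)
        n_live = max(n_live, 1)
        birth = int(rng.integers(0, max(1, p.n_frames - n_live + 1)))
        start = rng.uniform((0, 0), (w, h))
        pos = _random_walk(rng, start, n_live, p.diffusion_coefficient, p.field_size)
        ia = rng.normal(p.spurious_intensity, p.intensity_noise_sd, n_live)
        id_ = p.background_rate + rng.normal(0.0, p.intensity_noise_sd, n_live)
        frames = birth + np.arange(n_live)
        for t in range(n_live):
            self.det_rows[ACCEPTOR].append((frames[t], pos[t, 0], pos[t, 1], ia[t], traj_id))
        self.trajs.append(
            DonorAcceptorTrajectory(
                id=traj_id, cell_id=cell_id, condition=condition, frames=frames,
                acceptor_xy=pos, donor_xy=pos.copy(),
                acceptor_intensity=ia, donor_intensity=id_,
            )
        )
        nan = np.full(n_live, np.nan)
        self.truth.per_trajectory[traj_id] = TrajectoryTruth(
            kind="spurious", states=np.full(n_live, -1, dtype=np.int64),
            efficiency=nan, bleach_index=None,
            crossing_frames_acceptor=np.empty(0, dtype=np.int64),
            crossing_frames_donor=np.empty(0, dtype=np.int64),
            intrinsic_donor=np.zeros(n_live), intrinsic_acceptor=np.full(n_live, np.nan),
        )

    # -- assembly -----------------------------------------------------------

    def finish(self) -> Scene:
        cols = ["frame", "x", "y", "intensity", "particle"]
        don = pd.DataFrame(self.det_rows[DONOR], columns=cols)
        acc = pd.DataFrame(self.det_rows[ACCEPTOR], columns=cols)
        for df in (don, acc):
            df["frame"] = df["frame"].astype(np.int64)
        self._fill_crossings(don, acc)
        return Scene(
            params=self.params, donor_detections=don, acceptor_detections=acc,
            trajectories=self.trajs, truth=self.truth,
        )

    def _fill_crossings(self, don: pd.DataFrame, acc: pd.DataFrame) -> None:
        """Brute-force O(frames x detections) crossing ledger.

        A frame is a crossing frame in a channel when more than one of that
        channel's detections lies strictly within d_min of the pair position
        (the pair's own detection, when present, contributes one count).
        """
        d_min = self.params.d_min_px
        by_frame = {}
        for ch, df in ((DONOR, don), (ACCEPTOR, acc)):
            by_frame[ch] = {
                int(f): g[["x", "y"]].to_numpy(dtype=float)
                for f, g in df.groupby("frame")
            }
        for traj in self.trajs:
            t_truth = self.truth.per_trajectory[traj.id]
            crossings = {DONOR: [], ACCEPTOR: []}
            for k in range(len(traj)):
                f = int(traj.frames[k])
                x, y = traj.acceptor_xy[k]
                for ch in (DONOR, ACCEPTOR):
                    pts = by_frame[ch].get(f)
                    if pts is None:
                        continue
                    dist = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
                    if int(np.count_nonzero(dist < d_min)) > 1:
                        crossings[ch].append(f)
            t_truth.crossing_frames_acceptor = np.asarray(crossings[ACCEPTOR], dtype=np.int64)
            t_truth.crossing_frames_donor = np.asarray(crossings[DONOR], dtype=np.int64)


def simulate_scene(params: SceneParams) -> Scene:
    """Generate a full synthetic scene; bitwise reproducible for a fixed seed."""
    b = _SceneBuilder(params)
    p = params
    rng = b.rng
    w, h = p.field_size
    for i in range(p.n_fret_pairs):
        birth = int(rng.integers(0, max(1, p.n_frames - 25)))
        n_max = p.n_frames - birth
        trans = p.transition_matrix()
        # lifetime is drawn against a pre-drawn state path so that the track-loss
        # hazard can depend on the FRET level (high-FRET tracks persist longer)
        path = _markov_states(rng, trans, n_max)
        n_live = max(1, _pair_lifetime(rng, p, path, n_max))
        start = rng.uniform((0, 0), (w, h))
        bleach_index = None
        if p.acceptor_bleach_prob_per_frame > 0:
            g = int(rng.geometric(p.acceptor_bleach_prob_per_frame))
            if g < n_live:
                bleach_index = g
        b.add_pair(f"pair{i:04d}", birth, n_live, start, bleach_index, states=path)
    n_donly = int(round(p.donor_only_density * w * h / 1e4))
    for j in range(n_donly):
        b.add_donor_only(f"donly{j:04d}")
    for s in range(p.n_spurious_acceptor_tracks):
        b.add_spurious_acceptor(f"spur{s:04d}")
    return b.finish()


def plant_bleach_templates(
    params: SceneParams,
    n_templates: int,
    n_correlated: int = 0,
    w_pre: int = 10,
    w_post: int = 10,
) -> Scene:
    """A scene whose first pairs are forced to bleach mid-trajectory.

    ``n_templates`` pairs bleach anti-correlated (acceptor falls, donor
    rises) and ``n_correlated`` pairs co-bleach (both fall) — the latter are
    negative controls for template selection.  Planted pairs are laid out on
    a jittered grid with at least 5*d_min spacing (the field is enlarged if
    needed) so that, absent other particles, they are crossover-free; each
    has at least ``w_pre`` frames before and ``w_post`` after its bleach.
    Remaining pairs, donor-only particles and spurious tracks follow
    ``params`` unchanged.
    """
    if n_templates + n_correlated > params.n_fret_pairs:
        raise ValidationError("more planted bleachers than FRET pairs")
    n_planted = n_templates + n_correlated
    spacing = 5.0 * params.d_min_px
    cols = max(1, math.ceil(math.sqrt(n_planted))) if n_planted else 1
    rows = math.ceil(n_planted / cols) if n_planted else 1
    need_w = cols * spacing + spacing
    need_h = rows * spacing + spacing
    w, h = params.field_size
    if w < need_w or h < need_h:
        params = SceneParams(**{**params.__dict__,
                                "field_size": (max(w, int(need_w)), max(h, int(need_h)))})
    min_len = max(20, w_pre + w_post + 2) + 20
    if params.n_frames < min_len + 1:
        raise ValidationError(f"n_frames must be at least {min_len + 1} to host windows")
    b = _SceneBuilder(params)
    rng = b.rng
    w, h = params.field_size
    for i in range(n_planted):
        gx = (i % cols + 1) * spacing
        gy = (i // cols + 1) * spacing
        start = np.array([gx, gy]) + rng.uniform(-2, 2, 2)
        n_live = int(min_len + rng.integers(0, 20))
        birth = int(rng.integers(0, max(1, params.n_frames - n_live + 1)))
        bleach_index = int(rng.integers(max(20, w_pre + 1), n_live - w_post - 1))
        kind = "template" if i < n_templates else "correlated"
        b.add_pair(f"{kind}{i:04d}", birth, n_live, start, bleach_index, kind=kind)
    for i in range(n_planted, params.n_fret_pairs):
        birth = int(rng.integers(0, max(1, params.n_frames - 25)))
        n_max = params.n_frames - birth
        path = _markov_states(rng, params.transition_matrix(), n_max)
        n_live = max(1, _pair_lifetime(rng, params, path, n_max))
        start = rng.uniform((0, 0), (w, h))
        b.add_pair(f"pair{i:04d}", birth, n_live, start, None)
    n_donly = int(round(params.donor_only_density * w * h / 1e4))
    for j in range(n_donly):
        b.add_donor_only(f"donly{j:04d}")
    for s in range(params.n_spurious_acceptor_tracks):
        b.add_spurious_acceptor(f"spur{s:04d}")
    return b.finish()


def render_stacks(
    scene: Scene,
    psf_sd: float = 1.0,
    poisson_noise: bool = True,
    background: float = 5.0,
    seed: int | None = None,
):
    """Render per-channel image stacks from the detection tables.

    Each detection contributes an integrated 2-D Gaussian PSF (sd in
    pixels) whose total flux equals its intensity; a constant background is
    added, then optional Poisson noise.  Returns (donor, acceptor)
    :class:`~smfret_curate.roi.ImageStack` objects.
    """
    from .roi import ImageStack
    from scipy.special import erf

    p = scene.params
    w, h = int(p.field_size[0]), int(p.field_size[1])
    rng = np.random.default_rng(p.seed if seed is None else seed)
    n_frames = int(
        max(
            scene.donor_detections["frame"].max() if len(scene.donor_detections) else 0,
            scene.acceptor_detections["frame"].max() if len(scene.acceptor_detections) else 0,
        )
        + 1
    )
    out = {}
    xs = np.arange(w)
    ys = np.arange(h)
    for ch, df in ((DONOR, scene.donor_detections), (ACCEPTOR, scene.acceptor_detections)):
        stack = np.full((n_frames, h, w), float(background))
        for row in df.itertuples(index=False):
            flux = max(float(row.intensity), 0.0)
            if flux == 0.0:
                continue
            # integrated Gaussian over pixel edges; pixel i spans [i-0.5, i+0.5]
            cx = erf((xs + 0.5 - row.x) / (psf_sd * np.sqrt(2))) - erf(
                (xs - 0.5 - row.x) / (psf_sd * np.sqrt(2))
            )
            cy = erf((ys + 0.5 - row.y) / (psf_sd * np.sqrt(2))) - erf(
                (ys - 0.5 - row.y) / (psf_sd * np.sqrt(2))
            )
            stack[int(row.frame)] += flux * 0.25 * np.outer(cy, cx)
        if poisson_noise:
            stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
        out[ch] = ImageStack(frames=stack, channel=ch)
    return out[DONOR], out[ACCEPTOR]
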