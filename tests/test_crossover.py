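"""Per-frame crossing-over densities, the keep mask, stitching, summaries."""

import numpy as np
import pandas as pd
import pytest

from smfret_curate.crossover import (
    DetectionIndex,
    density_profile,
    distances_at_frame,
    profiles_from_frame,
    profiles_to_frame,
    stitch_kept_frames,
    summarize_crossovers,
)
from smfret_curate.model import Detection
from conftest import make_profile, make_trajectory


def det(channel, frame, x, y, intensity=100.0):
    return Detection(channel, frame, x, y, intensity)


def index_of(*dets):
    return DetectionIndex(list(dets))


class TestDistances:
    def test_identical_position_gives_zero(self):
        traj = make_trajectory(n=30)
        x, y = traj.acceptor_xy[0]
        d = distances_at_frame(traj, 0, index_of(det("acceptor", 0, x, y)))
        np.testing.assert_allclose(d, [0.0])

    def test_three_four_five_triangle(self):
        traj = make_trajectory(n=30)
        x, y = traj.acceptor_xy[2]
        d = distances_at_frame(traj, 2, index_of(det("acceptor", 2, x + 3, y + 4)))
        np.testing.assert_allclose(d, [5.0])

    def test_no_detections_gives_empty(self):
        traj = make_trajectory(n=30)
        assert len(distances_at_frame(traj, 0, index_of())) == 0

    def test_frame_not_in_trajectory(self):
        traj = make_trajectory(n=30)
        with pytest.raises(IndexError):
            distances_at_frame(traj, 999, index_of())

    def test_matches_per_point_hypot_loop(self, rng):
        traj = make_trajectory(n=30, seed=7)
        x, y = traj.acceptor_xy[5]
        dets = [
            det("donor", 5, float(px), float(py))
            for px, py in rng.uniform(0, 60, size=(50, 2))
        ]
        got = np.sort(distances_at_frame(traj, 5, index_of(*dets)))
        expected = np.sort([np.hypot(d.x - x, d.y - y) for d in dets])
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestDensityProfile:
    def own_detections(self, traj, channel):
        return [
            det(channel, int(f), float(x), float(y))
            for f, (x, y) in zip(traj.frames, traj.acceptor_xy)
        ]

    def test_own_acceptor_detection_gives_density_one(self):
        traj = make_trajectory(n=25)
        prof = density_profile(
            traj, index_of(*self.own_detections(traj, "acceptor")), index_of(), d_min=6.0
        )
        np.testing.assert_array_equal(prof.rho_acceptor, np.ones(25))
        assert prof.keep_mask.all()

    def test_interloper_inside_radius_drops_frame(self):
        traj = make_trajectory(n=25)
        x, y = traj.acceptor_xy[3]
        acc = self.own_detections(traj, "acceptor") + [det("acceptor", 3, x + 5, y)]
        prof = density_profile(traj, index_of(*acc), index_of(), d_min=6.0)
        assert prof.rho_acceptor[3] == 2
        assert not prof.keep_mask[3]
        assert prof.keep_mask.sum() == 24

    def test_interloper_at_exactly_d_min_not_counted(self):
        traj = make_trajectory(n=25)
        x, y = traj.acceptor_xy[3]
        acc = self.own_detections(traj, "acceptor") + [det("acceptor", 3, x + 6.0, y)]
        prof = density_profile(traj, index_of(*acc), index_of(), d_min=6.0)
        assert prof.rho_acceptor[3] == 1
        assert prof.keep_mask[3]

    def test_quenched_donor_frame_kept_with_zero_density(self):
        traj = make_trajectory(n=25)
        prof = density_profile(
            traj, index_of(*self.own_detections(traj, "acceptor")), index_of(), d_min=6.0
        )
        np.testing.assert_array_equal(prof.rho_donor, np.zeros(25))
        assert prof.keep_mask.all()

    def test_density_monotone_in_d_min_and_kept_antitone(self, rng):
        traj = make_trajectory(n=40, seed=3)
        dets = [
            det("donor", int(f), float(px), float(py))
            for f in traj.frames
            for px, py in rng.uniform(0, 60, size=(4, 2))
        ]
        idx = index_of(*dets)
        prev_rho = None
        prev_kept = None
        for d_min in (2.0, 4.0, 8.0, 16.0):
            prof = density_profile(traj, index_of(), idx, d_min=d_min)
            if prev_rho is not None:
                assert np.all(prof.rho_donor >= prev_rho)
                assert prof.n_kept <= prev_kept
            prev_rho = prof.rho_donor
            prev_kept = prof.n_kept

    def test_kept_plus_dropped_is_total(self, rng):
        traj = make_trajectory(n=40, seed=3)
        dets = [
            det("donor", int(f), float(px), float(py))
            for f in traj.frames
            for px, py in rng.uniform(0, 60, size=(3, 2))
        ]
        prof = density_profile(traj, index_of(), index_of(*dets), d_min=6.0)
        assert prof.n_kept + prof.n_dropped == len(traj)


class TestStitch:
    def test_all_true_mask_is_identity_one_segment(self):
        traj = make_trajectory(n=10)
        kept, segments = stitch_kept_frames(traj, make_profile(traj))
        assert len(kept) == 10
        assert segments == [(0, 10)]
        np.testing.assert_array_equal(kept.acceptor_intensity, traj.acceptor_intensity)

    def test_interior_drop_splits_segments(self):
        traj = make_trajectory(n=4)
        kept, segments = stitch_kept_frames(
            traj, make_profile(traj, keep=[True, True, False, True])
        )
        assert len(kept) == 3
        assert segments == [(0, 2), (3, 4)]

    def test_all_false_mask_gives_empty(self):
        traj = make_trajectory(n=5)
        kept, segments = stitch_kept_frames(traj, make_profile(traj, keep=np.zeros(5, bool)))
        assert len(kept) == 0 and segments == []


class TestSummary:
    def test_clean_profiles_all_zero_counts(self):
        trajs = [make_trajectory(n=20, traj_id=f"t{i}") for i in range(2)]
        s = summarize_crossovers([make_profile(t) for t in trajs])
        assert s.n_trajectories == 2 and s.n_frames_total == 40
        assert s.n_frames_multi_donor == 0 and s.n_frames_multi_acceptor == 0
        assert s.n_traj_acceptor_multi_near_end == 0

    def test_acceptor_crossover_at_final_frame_counts_near_end(self):
        traj = make_trajectory(n=20)
        rho_acc = np.ones(20, dtype=int)
        rho_acc[-1] = 2
        prof = make_profile(traj, keep=rho_acc <= 1, rho_acc=rho_acc)
        s = summarize_crossovers([prof], end_window=5)
        assert s.n_traj_acceptor_multi_near_end == 1
        assert s.n_frames_multi_acceptor == 1

    def test_random_profiles_match_brute_force_recount(self, rng):
        profiles = []
        for i in range(20):
            traj = make_trajectory(n=int(rng.integers(20, 40)), traj_id=f"t{i}", seed=i)
            rho_a = rng.integers(0, 3, len(traj))
            rho_d = rng.integers(0, 4, len(traj))
            profiles.append(
                make_profile(traj, keep=(rho_a <= 1) & (rho_d <= 1), rho_acc=rho_a, rho_don=rho_d)
            )
        s = summarize_crossovers(profiles, end_window=5)
        exp_multi_d = sum(sum(1 for v in p.rho_donor if v > 1) for p in profiles)
        exp_multi_a = sum(sum(1 for v in p.rho_acceptor if v > 1) for p in profiles)
        exp_end = sum(
            1 for p in profiles if any(v > 1 for v in list(p.rho_acceptor)[-5:])
        )
        assert s.n_frames_multi_donor == exp_multi_d
        assert s.n_frames_multi_acceptor == exp_multi_a
        assert s.n_traj_acceptor_multi_near_end == exp_end


def test_profile_table_round_trip():
    trajs = [make_trajectory(n=21, traj_id=f"t{i}", seed=i) for i in range(3)]
    profiles = [make_profile(t, keep=np.arange(21) % 3 > 0) for t in trajs]
    back = profiles_from_frame(profiles_to_frame(profiles))
    for orig, rt in zip(profiles, back):
        assert rt.traj_id == orig.traj_id
        np.testing.assert_array_equal(rt.keep_mask, orig.keep_mask)
        np.testing.assert_array_equal(rt.rho_donor, orig.rho_donor)
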