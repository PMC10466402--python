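"""Bleach detection, auROC, template selection, thresholds, region labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smfret_curate.fret import IntensitySummary
from smfret_curate.thresholds import (
    TemplateSelectionError,
    Thresholds,
    auroc,
    classify_region,
    compute_bleach_events,
    detect_bleach_frame,
    infer_thresholds,
    select_templates,
)
from conftest import make_profile, make_trajectory


class TestBleachDetection:
    def test_clean_step_found_at_first_low_frame(self):
        assert detect_bleach_frame([500, 500, 500, 20, 20, 20], noise_floor=60) == 3

    def test_constant_trace_has_no_step(self):
        assert detect_bleach_frame([500.0] * 10, noise_floor=60) is None

    def test_blinking_recovery_fails_persistence(self):
        trace = [500, 500, 20, 500, 500, 500, 500]
        assert detect_bleach_frame(trace, noise_floor=60) is None

    def test_noisy_steps_recovered_within_one_frame(self, rng):
        """Planted single steps at SNR >= 5 are located to +-1 frame >=95%."""
        hits = 0
        n_traces = 200
        for i in range(n_traces):
            n = 80
            t_true = int(rng.integers(15, 65))
            trace = np.where(np.arange(n) < t_true, 500.0, 0.0)
            trace = trace + rng.normal(0, 50, n)  # step SNR = 10
            got = detect_bleach_frame(trace, noise_floor=150.0)
            if got is not None and abs(got - t_true) <= 1:
                hits += 1
        assert hits / n_traces >= 0.95


class TestAuroc:
    def test_complete_rise_is_one(self):
        trace = [1, 1, 1, 0, 5, 5, 5]
        assert auroc(trace, 3, w_pre=3, w_post=3) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([4.0] * 9, 4, w_pre=3, w_post=3) == 0.5

    def test_worked_seven_ninths_case(self):
        trace = [1, 2, 3, 0, 2, 3, 4]
        assert auroc(trace, 3, w_pre=3, w_post=3) == pytest.approx(7 / 9)

    def test_window_exceeding_trace_gives_none(self):
        assert auroc([1, 2, 3], 1, w_pre=2, w_post=2) is None

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(50):
            trace = rng.normal(0, 1, 25)
            got = auroc(trace, 12, w_pre=8, w_post=8)
            pre, post = trace[4:12], trace[13:21]
            brute = sum(
                1.0 if b > a else (0.5 if b == a else 0.0) for b in post for a in pre
            ) / 64.0
            assert got == pytest.approx(brute, abs=1e-12)

    def test_reversal_complements_in_absence_of_ties(self, rng):
        trace = rng.normal(0, 1, 30)
        fwd = auroc(trace, 15, 10, 10)
        rev = auroc(trace[::-1], 14, 10, 10)  # mirror index of frame 15
        assert fwd + rev == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100, allow_nan=False).map(lambda v: round(v, 3)),
                    min_size=9, max_size=9),
           st.floats(0.1, 5.0), st.floats(-10, 10))
    def test_in_unit_interval_and_monotone_transform_invariant(self, vals, scale, shift):
        # values on a 1e-3 grid so the affine map cannot erase distinctions
        # within double precision
        trace = np.array(vals)
        a = auroc(trace, 4, 4, 4)
        assert 0.0 <= a <= 1.0
        assert auroc(scale * trace + shift, 4, 4, 4) == pytest.approx(a)


def bleacher(traj_id="tpl", n=60, b=30, e=0.5, i0=1000.0, noise=20.0,
             correlated=False, seed=0):
    """A trajectory with a planted acceptor bleach at positional index b."""
    rng = np.random.default_rng(seed)
    acc = np.where(np.arange(n) < b, e * i0, 0.0) + rng.normal(0, noise, n)
    if correlated:
        don = np.where(np.arange(n) < b, (1 - e) * i0, 0.0) + rng.normal(0, noise, n)
    else:
        don = np.where(np.arange(n) < b, (1 - e) * i0, i0) + rng.normal(0, noise, n)
    return make_trajectory(n=n, traj_id=traj_id, acc_intensity=acc, don_intensity=don)


class TestTemplateSelection:
    def events(self, trajs):
        return compute_bleach_events(trajs, noise_floor=150.0, w_pre=10, w_post=10)

    def test_anticorrelated_bleacher_selected(self):
        trajs = [bleacher()]
        tmpl = select_templates(trajs, {"tpl": make_profile(trajs[0])}, self.events(trajs))
        assert tmpl == {"tpl"}

    def test_trajectory_with_any_dropped_frame_excluded(self):
        trajs = [bleacher(), bleacher(traj_id="crossed", seed=1)]
        keep = np.ones(60, bool)
        keep[10] = False
        profiles = {
            "tpl": make_profile(trajs[0]),
            "crossed": make_profile(trajs[1], keep=keep),
        }
        tmpl = select_templates(trajs, profiles, self.events(trajs))
        assert tmpl == {"tpl"}

    def test_correlated_cobleacher_excluded_by_donor_criterion(self):
        trajs = [bleacher(), bleacher(traj_id="corr", correlated=True, seed=2)]
        events = self.events(trajs)
        assert events["corr"].auroc_donor < 0.5  # donor fell with the acceptor
        profiles = {t.id: make_profile(t) for t in trajs}
        assert select_templates(trajs, profiles, events) == {"tpl"}

    def test_empty_template_set_is_hard_error(self):
        trajs = [bleacher(traj_id="corr", correlated=True)]
        profiles = {t.id: make_profile(t) for t in trajs}
        with pytest.raises(TemplateSelectionError, match="relax"):
            select_templates(trajs, profiles, self.events(trajs))


class TestInferThresholds:
    def test_single_template_extrema(self):
        n, b = 40, 20
        acc = np.full(n, 400.0)
        acc[b:] = 0.0
        don = np.full(n, 500.0)
        don[b:] = 600.0
        don[b + 1 : b + 4] = [900.0, 950.0, 920.0]
        traj = make_trajectory(n=n, traj_id="tpl", acc_intensity=acc, don_intensity=don)
        events = {
            "tpl": compute_bleach_events([traj], noise_floor=100.0, w_pre=5, w_post=3)["tpl"]
        }
        assert events["tpl"].t_bleach == b
        th = infer_thresholds({"tpl"}, [traj], events, w_post=3)
        assert th.acceptor_min == 400.0
        assert th.donor_max == 950.0
        assert th.total_max == 1350.0

    def test_two_templates_elementwise_extrema(self):
        def tpl(traj_id, mean_acc, donor_peak, seed):
            n, b = 40, 20
            acc = np.full(n, mean_acc)
            acc[b:] = 0.0
            don = np.full(n, 500.0)
            don[b:] = donor_peak
            return make_trajectory(n=n, traj_id=traj_id, acc_intensity=acc, don_intensity=don)

        trajs = [tpl("a", 400.0, 900.0, 0), tpl("b", 300.0, 1100.0, 1)]
        events = compute_bleach_events(trajs, noise_floor=100.0, w_pre=5, w_post=5)
        th = infer_thresholds({"a", "b"}, trajs, events, w_post=5)
        assert th.acceptor_min == 300.0 and th.donor_max == 1100.0

    def test_adding_template_grows_donor_max_and_shrinks_acceptor_min(self, rng):
        trajs = [bleacher(traj_id=f"t{i}", e=0.3 + 0.05 * i, seed=i) for i in range(6)]
        events = compute_bleach_events(trajs, noise_floor=150.0, w_pre=10, w_post=10)
        ids = sorted(events)
        prev = None
        for k in range(1, len(ids) + 1):
            th = infer_thresholds(set(ids[:k]), trajs, events, w_post=10)
            if prev is not None:
                assert th.donor_max >= prev.donor_max
                assert th.acceptor_min <= prev.acceptor_min
            prev = th

    def test_empty_set_rejected(self):
        with pytest.raises(TemplateSelectionError):
            infer_thresholds(set(), [], {}, w_post=10)


class TestClassifyRegion:
    TH = Thresholds(acceptor_min=200.0, donor_max=2000.0)

    def summary(self, acc, don):
        return IntensitySummary(traj_id="s", mean_donor=don, mean_acceptor=acc, n_kept=10)

    @pytest.mark.parametrize(
        "acc,don,expected",
        [
            (800.0, 100.0, "high"),     # r ~ 0.889
            (150.0, 100.0, "rejected"),  # below acceptor_min
            (400.0, 400.0, "medium"),   # r = 0.5
            (100.0, 900.0, "rejected"),  # acc below floor
            (250.0, 1000.0, "low"),     # r = 0.2
            (1300.0, 1000.0, "rejected"),  # total above total_max (2200)
        ],
    )
    def test_worked_examples(self, acc, don, expected):
        assert classify_region(self.summary(acc, don), self.TH) == expected

    def test_boundary_ratios_fall_to_lower_region(self):
        # r exactly 0.7 -> medium; r exactly 0.3 -> low
        assert classify_region(self.summary(700.0, 300.0), self.TH) == "medium"
        assert classify_region(self.summary(300.0, 700.0), self.TH) == "low"

    def test_matches_independent_inequality_evaluation(self, rng):
        th = self.TH
        for _ in range(1000):
            acc = float(rng.uniform(0, 2500))
            don = float(rng.uniform(0, 2500))
            got = classify_region(self.summary(acc, don), th)
            if acc <= th.acceptor_min or acc + don >= th.total_max:
                expected = "rejected"
            else:
                r = acc / (acc + don)
                expected = "high" if r > 0.7 else ("medium" if r > 0.3 else "low")
            assert got == expected

    def test_partition_exhaustive_and_exclusive(self, rng):
        labels = {"high", "medium", "low", "rejected"}
        for _ in range(500):
            s = self.summary(float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000)))
            assert classify_region(s, self.TH) in labels
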