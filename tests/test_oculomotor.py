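"""Preprocessing, velocity computation and saccade/fixation detection."""

import numpy as np
import pytest

from gart.oculomotor import (
    BinocularTrace,
    DetectorParams,
    MonocularTrace,
    adaptive_threshold,
    compute_velocity,
    detect_events,
    preprocess,
    summarize_saccades,
)
from gart.session import Phase, build_phase_schedule
from gart.simulate import render_fixation_sequence

FS = 50.0
DT = 1.0 / FS


def straight(n):
    d = np.zeros((n, 3))
    d[:, 2] = 1.0
    return d


def binocular(t, d, vl=None, vr=None):
    n = len(t)
    return BinocularTrace(
        t=t, left=d.copy(), right=d.copy(),
        valid_left=np.ones(n, bool) if vl is None else vl,
        valid_right=np.ones(n, bool) if vr is None else vr,
    )


class TestPreprocess:
    def test_short_both_eye_gap_is_interpolated(self):
        t = np.arange(100) * DT
        vl = np.ones(100, bool)
        vl[50:52] = False  # 40 ms gap
        bt = binocular(t, straight(100), vl=vl.copy(), vr=vl.copy())
        mono = preprocess(bt)
        assert mono.valid.all()
        assert mono.data_loss_pct == 0.0

    def test_long_gap_remains_invalid(self):
        t = np.arange(100) * DT
        vl = np.ones(100, bool)
        vl[40:51] = False  # 220 ms gap
        bt = binocular(t, straight(100), vl=vl.copy(), vr=vl.copy())
        mono = preprocess(bt)
        assert not mono.valid[45]
        assert mono.data_loss_pct > 0

    def test_one_eye_loss_compensated_from_other(self):
        t = np.arange(100) * DT
        d_r = straight(100)
        d_l = np.roll(d_r, 1, axis=1)  # junk left data, all invalid
        bt = BinocularTrace(t=t, left=d_l, right=d_r,
                            valid_left=np.zeros(100, bool),
                            valid_right=np.ones(100, bool))
        mono = preprocess(bt)
        assert mono.valid.all()
        assert np.allclose(mono.direction, d_r)

    def test_interpolated_directions_renormalized(self):
        t = np.arange(10) * DT
        d = straight(10)
        d[6:] = [1.0, 0.0, 0.0]  # right-angle turn across the gap
        v = np.ones(10, bool)
        v[5] = False
        bt = binocular(t, d, vl=v.copy(), vr=v.copy())
        mono = preprocess(bt)
        assert np.linalg.norm(mono.direction[5]) == pytest.approx(1.0)

    def test_all_invalid_trace_is_an_error(self):
        t = np.arange(10) * DT
        bt = binocular(t, straight(10), vl=np.zeros(10, bool),
                       vr=np.zeros(10, bool))
        with pytest.raises(ValueError, match="no valid samples"):
            preprocess(bt)


class TestVelocity:
    def test_constant_direction_gives_zero_velocity(self):
        t = np.arange(50) * DT
        mono = MonocularTrace(t, straight(50), np.ones(50, bool), 0.0)
        vt = compute_velocity(mono)
        assert np.allclose(vt.velocity, 0.0, atol=1e-9)

    def test_constant_rotation_recovered_within_2pct(self):
        # 10 deg/s rotation about the y axis
        t = np.arange(200) * DT
        ang = np.deg2rad(10.0) * t
        d = np.stack([np.sin(ang), np.zeros_like(ang), np.cos(ang)], axis=1)
        mono = MonocularTrace(t, d, np.ones(len(t), bool), 0.0)
        vt = compute_velocity(mono)
        mid = vt.velocity[10:-10]
        assert np.allclose(mid, 10.0, rtol=0.02)

    def test_single_sample_step_peak_velocity(self):
        # 5 deg step in one 20 ms sample -> 250 deg/s raw peak
        t = np.arange(20) * DT
        d = straight(20)
        a = np.deg2rad(5.0)
        d[10:] = [np.sin(a), 0.0, np.cos(a)]
        mono = MonocularTrace(t, d, np.ones(20, bool), 0.0)
        vt = compute_velocity(mono)
        assert vt.raw_velocity.max() == pytest.approx(250.0, rel=1e-6)

    def test_too_short_trace_rejected(self):
        t = np.arange(3) * DT
        mono = MonocularTrace(t, straight(3), np.ones(3, bool), 0.0)
        with pytest.raises(ValueError, match="too short"):
            compute_velocity(mono)


class TestAdaptiveThreshold:
    def test_constant_velocities_are_a_fixed_point(self):
        assert adaptive_threshold(np.full(100, 42.0)) == pytest.approx(42.0)

    def test_bimodal_distribution_separated(self, rng):
        v = np.concatenate([
            np.abs(rng.normal(5, 2, 2000)),   # fixation noise
            rng.normal(300, 30, 100),         # saccade peaks
        ])
        pt = adaptive_threshold(v)
        assert 5 < pt < 300

    def test_deterministic(self, rng):
        v = np.abs(rng.normal(10, 5, 500))
        assert adaptive_threshold(v) == adaptive_threshold(v)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.array([]))


class TestDetection:
    def test_constant_trace_is_one_fixation_no_saccades(self):
        t = np.arange(200) * DT
        mono = MonocularTrace(t, straight(200), np.ones(200, bool), 0.0)
        sac, fix = detect_events(mono, threshold=50.0)
        assert sac == []
        assert len(fix) == 1
        assert fix[0].start == t[0] and fix[0].end == t[-1]

    def test_three_step_shifts_found_at_known_times(self):
        t, d, bounds = render_fixation_sequence(
            [0.5, 0.5, 0.5, 0.5], [0.02, 0.02, 0.02], seed=1)
        mono = MonocularTrace(t, d, np.ones(len(t), bool), 0.0)
        sac, fix = detect_events(mono)
        assert len(sac) == 3
        for s, gt_end in zip(sac, bounds[:-1, 1]):
            assert abs(s.start - gt_end) <= 3 * DT
        assert len(fix) == 4

    def test_short_candidate_fixation_discarded(self):
        # 50 ms fixation between two saccades must not be retained
        t, d, _ = render_fixation_sequence(
            [0.5, 0.05, 0.5], [0.04, 0.04], seed=2)
        mono = MonocularTrace(t, d, np.ones(len(t), bool), 0.0)
        _, fix = detect_events(mono)
        assert all(f.duration_ms >= 60.0 for f in fix)
        assert len(fix) == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_min_duration_and_merge_invariants_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        nf = 40
        fd = rng.uniform(0.03, 0.45, nf)
        gd = rng.uniform(0.02, 0.2, nf - 1)
        t, d, _ = render_fixation_sequence(fd, gd, seed=seed)
        mono = MonocularTrace(t, d, np.ones(len(t), bool), 0.0)
        sac, fix = detect_events(mono)
        params = DetectorParams()
        for f in fix:
            assert f.duration_ms >= params.min_fixation * 1000 - 1e-9
        for f1, f2 in zip(fix, fix[1:]):
            assert (f2.start - f1.end) > params.merge_interval - 1e-9
        # no saccade/fixation overlap
        events = sorted([(s.start, s.end) for s in sac]
                        + [(f.start, f.end) for f in fix])
        for (a1, b1), (a2, b2) in zip(events, events[1:]):
            assert b1 <= a2 + 1e-9

    def test_recovers_at_least_95pct_of_2deg_saccades(self):
        nf = 100
        rng = np.random.default_rng(9)
        fd = rng.uniform(0.2, 0.5, nf)
        gd = np.full(nf - 1, 0.02)
        t, d, _ = render_fixation_sequence(fd, gd, seed=9,
                                           amplitude_deg=(2.0, 12.0))
        mono = MonocularTrace(t, d, np.ones(len(t), bool), 0.0)
        sac, _ = detect_events(mono)
        assert len(sac) >= 0.95 * (nf - 1)

    def test_zero_detections_on_pure_noise(self, rng):
        from gart.simulate import _jitter_dirs
        t = np.arange(0, 60, DT)
        d = _jitter_dirs(np.random.default_rng(4), np.array([0, 0, 1.0]),
                         len(t), 0.10)
        mono = MonocularTrace(t, d, np.ones(len(t), bool), 0.0)
        sac, _ = detect_events(mono)
        assert sac == []

    def test_injected_data_loss_reported_within_half_percent(self):
        from gart.scene import default_scene, distractor_schedule
        from gart.simulate import (ADHD_PROFILE, render_gaze,
                                   simulate_attention)
        sched = build_phase_schedule(Phase.DP, 2, 90.0)
        acts = distractor_schedule(sched, seed=0)
        scn = default_scene()
        losses, injected = [], []
        for seed in range(4):
            track = simulate_attention(ADHD_PROFILE, sched, acts, seed=seed)
            trace, _ = render_gaze(track, scn, acts, seed=seed)
            mono = preprocess(trace)
            occ = track.occupancy()
            injected.append(100.0 * occ.get("blink", 0.0))
            losses.append(mono.data_loss_pct)
        # blink episodes exceed the 75 ms interpolation bound, so the
        # reported loss should track the injected blink time closely
        assert np.mean(losses) == pytest.approx(np.mean(injected), abs=0.5)


class TestSummary:
    def test_counts_conserve_and_empty_cells_are_nan(self):
        sched = build_phase_schedule(Phase.DP, 2, 30.0)
        t, d, _ = render_fixation_sequence(
            [10.0, 10.0, 10.0], [0.06, 0.06], seed=3)
        mono = MonocularTrace(t, d, np.ones(len(t), bool), 0.0)
        sac, _ = detect_events(mono)
        summ = summarize_saccades(sac, sched)
        assert summ[Phase.DP]["count"] + summ[Phase.NDP]["count"] == len(sac)
        empty = summarize_saccades([], sched)
        assert empty[Phase.DP]["count"] == 0
        assert np.isnan(empty[Phase.DP]["mean_duration_ms"])
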