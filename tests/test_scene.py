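"""Ray-collider classification, distractor scheduling, dwell analysis."""

import numpy as np
import pytest

from gart.scene import (
    Collider,
    GazeState,
    GazeStateInterval,
    Scene,
    classify_gaze_sample,
    classify_gaze_stream,
    default_scene,
    distractor_schedule,
    dwell_summary,
    intervals_from_samples,
)
from gart.session import Phase, build_phase_schedule

ORIGIN = np.array([0.0, 1.2, 0.0])


def simple_scene():
    return Scene([
        Collider("canvas", "canvas", "box",
                 center=[0.0, 1.2, 3.0], extent=[1.0, 0.75, 0.05]),
        Collider("d_box", "distractor", "box",
                 center=[2.0, 1.2, 1.0], extent=[0.3, 0.3, 0.3],
                 active_windows=[(0.0, 10.0)]),
        Collider("d_sph", "distractor", "sphere",
                 center=[-2.0, 1.0, 1.5], extent=[0.4, 0.0, 0.0],
                 active_windows=[(0.0, 10.0)]),
    ])


class TestDistractorSchedule:
    def test_six_per_dp_at_30s_spacing(self):
        sched = build_phase_schedule(Phase.DP, 1, 180.0)
        acts = distractor_schedule(sched, interval=30.0, seed=0)
        assert len(acts) == 6
        assert [a.onset for a in acts] == [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]
        assert len({a.object_id for a in acts}) == 6  # without replacement

    def test_ndp_only_schedule_yields_no_events(self):
        sched = build_phase_schedule(Phase.NDP, 1, 180.0)
        assert distractor_schedule(sched, seed=0) == []

    def test_three_dps_give_18_deterministically(self):
        sched = build_phase_schedule(Phase.DP, 6, 180.0)
        a1 = distractor_schedule(sched, seed=42)
        a2 = distractor_schedule(sched, seed=42)
        assert len(a1) == 18
        assert [x.object_id for x in a1] == [x.object_id for x in a2]
        assert all(sched.phase_at(x.onset) == Phase.DP for x in a1)

    def test_spacing_is_exact_within_each_dp(self):
        sched = build_phase_schedule(Phase.DP, 6, 180.0)
        acts = distractor_schedule(sched, interval=30.0, seed=3)
        for pi in {a.phase_index for a in acts}:
            ons = sorted(a.onset for a in acts if a.phase_index == pi)
            assert np.allclose(np.diff(ons), 30.0)

    def test_interval_longer_than_phase_warns_and_yields_none(self):
        sched = build_phase_schedule(Phase.DP, 1, 20.0)
        with pytest.warns(UserWarning, match="no events"):
            acts = distractor_schedule(sched, interval=30.0, seed=0)
        assert acts == []


class TestClassification:
    def test_ray_at_canvas_center_is_task_focus(self):
        scn = simple_scene()
        d = np.array([0.0, 0.0, 1.0])
        state, hit = classify_gaze_sample(ORIGIN, d, scn, t=1.0)
        assert state == GazeState.TASK_FOCUS and hit == "canvas"

    def test_ray_at_active_distractor(self):
        scn = simple_scene()
        d = scn.collider("d_box").center - ORIGIN
        state, hit = classify_gaze_sample(ORIGIN, d, scn, t=1.0)
        assert state == GazeState.DISTRACTOR_FOCUS and hit == "d_box"
        # outside the activation window the same ray wanders
        state, hit = classify_gaze_sample(ORIGIN, d, scn, t=20.0)
        assert state == GazeState.GAZE_WANDERING

    def test_invalid_and_degenerate_samples(self):
        scn = simple_scene()
        state, _ = classify_gaze_sample(ORIGIN, [0, 0, 1], scn, 0.0,
                                        valid=False)
        assert state == GazeState.INVALID
        state, _ = classify_gaze_sample(ORIGIN, [0.0, 0.0, 0.0], scn, 0.0)
        assert state == GazeState.INVALID

    @pytest.mark.parametrize("shape_id", ["d_box", "d_sph"])
    def test_monte_carlo_inclusion_oracle(self, shape_id, rng):
        """Ray hit/miss agrees with dense point sampling along the ray."""
        scn = simple_scene()
        coll = scn.collider(shape_id)
        n = 10_000
        # aim into a cone around the collider so both labels occur often
        base = coll.center - ORIGIN
        base = base / np.linalg.norm(base)
        dirs = base + rng.normal(0, 0.25, size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ts = np.linspace(0.0, 8.0, 4000)
        ray_t = [coll.ray_intersect(ORIGIN, d) for d in dirs]
        hits_ray = np.array([h is not None for h in ray_t])
        hits_oracle = np.empty(n, dtype=bool)
        for lo in range(0, n, 500):
            chunk = dirs[lo:lo + 500]
            pts = ORIGIN[None, None, :] + ts[None, :, None] * chunk[:, None, :]
            if coll.shape == "sphere":
                inside = (np.linalg.norm(pts - coll.center, axis=2)
                          <= coll.extent[0])
            else:
                inside = np.all(np.abs(pts - coll.center) <= coll.extent,
                                axis=2)
            hits_oracle[lo:lo + 500] = inside.any(axis=1)
        # whenever the dense sampling finds an inside point the ray code
        # must report a hit...
        assert not np.any(hits_oracle & ~hits_ray)
        # ...and every reported hit must land on the collider (grazing rays
        # can slip between the oracle's sample points, so verify the exact
        # intersection point by inclusion instead)
        for i in np.nonzero(hits_ray)[0]:
            p = ORIGIN + ray_t[i] * dirs[i]
            if coll.shape == "sphere":
                assert np.linalg.norm(p - coll.center) <= \
                    coll.extent[0] + 1e-9
            else:
                assert np.all(np.abs(p - coll.center) <= coll.extent + 1e-9)
        # and the sampled oracle agrees on the overwhelming majority
        assert np.mean(hits_ray == hits_oracle) > 0.999

    def test_vectorized_stream_matches_scalar_classifier(self, rng):
        scn = simple_scene()
        n = 2000
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        t = np.arange(n) * 0.02
        valid = rng.uniform(size=n) > 0.05
        states_v, hits_v = classify_gaze_stream(
            t, np.tile(ORIGIN, (n, 1)), dirs, scn, valid=valid)
        for i in range(n):
            s, h = classify_gaze_sample(ORIGIN, dirs[i], scn, float(t[i]),
                                        bool(valid[i]))
            assert states_v[i] == s
            assert hits_v[i] == h

    def test_nearest_collider_wins(self):
        # a distractor box directly in front of the canvas occludes it
        scn = Scene([
            Collider("canvas", "canvas", "box",
                     center=[0.0, 1.2, 3.0], extent=[1.0, 0.75, 0.05]),
            Collider("front", "distractor", "box",
                     center=[0.0, 1.2, 1.5], extent=[0.2, 0.2, 0.2],
                     active_windows=[(0.0, 100.0)]),
        ])
        state, hit = classify_gaze_sample(ORIGIN, [0, 0, 1], scn, 1.0)
        assert state == GazeState.DISTRACTOR_FOCUS and hit == "front"


class TestIntervals:
    def test_constant_state_single_interval(self):
        t = np.arange(10) * 0.02
        ivs = intervals_from_samples(t, ["task_focus"] * 10)
        assert len(ivs) == 1
        assert ivs[0].duration == pytest.approx(t[-1] - t[0])

    def test_alternating_states_one_interval_per_sample(self):
        t = np.arange(6) * 0.02
        states = ["task_focus", "gaze_wandering"] * 3
        ivs = intervals_from_samples(t, states)
        assert len(ivs) == 5  # last sample span collapses into final interval

    @pytest.mark.parametrize("seed", range(5))
    def test_durations_sum_to_stream_span(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        t = np.cumsum(rng.uniform(0.01, 0.03, n))
        states = rng.choice(GazeState.ALL, size=n).tolist()
        ivs = intervals_from_samples(t, states)
        assert sum(iv.duration for iv in ivs) == pytest.approx(t[-1] - t[0])
        # contiguity and no two adjacent intervals share a state
        for a, b in zip(ivs, ivs[1:]):
            assert a.end == pytest.approx(b.start)
            assert a.state != b.state

    def test_unordered_input_rejected(self):
        with pytest.raises(ValueError):
            intervals_from_samples([0.0, 0.5, 0.4], ["a", "b", "c"])


class TestDwell:
    def test_pure_task_focus_scores_zero(self):
        ivs = [GazeStateInterval("task_focus", 0.0, 100.0)]
        d = dwell_summary(ivs, 100.0)
        assert d.pct_task_focus == 100.0
        assert d.distractibility_score == 0.0

    def test_80_5_15_gives_quarter(self):
        ivs = [GazeStateInterval("task_focus", 0.0, 80.0),
               GazeStateInterval("distractor_focus", 80.0, 85.0),
               GazeStateInterval("gaze_wandering", 85.0, 100.0)]
        d = dwell_summary(ivs, 100.0)
        assert d.distractibility_score == pytest.approx((5 + 15) / 80)

    @pytest.mark.parametrize("seed", range(5))
    def test_percentage_closure(self, seed):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(0.01, 0.05, 400))
        states = rng.choice(GazeState.ALL, size=400,
                            p=[0.7, 0.1, 0.15, 0.05]).tolist()
        ivs = intervals_from_samples(t - t[0], states)
        d = dwell_summary(ivs, float(t[-1] - t[0]))
        total = (d.pct_task_focus + d.pct_distractor_focus
                 + d.pct_gaze_wandering + d.pct_invalid)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_zero_task_focus_is_an_explicit_error(self):
        ivs = [GazeStateInterval("gaze_wandering", 0.0, 10.0)]
        with pytest.raises(ZeroDivisionError, match="undefined"):
            dwell_summary(ivs, 10.0)

    def test_adhd_profile_more_distractible_than_matched_hc(self):
        from gart.scene import apply_schedule_to_scene
        from gart.simulate import (ADHD_PROFILE, HC_PROFILE,
                                   simulate_attention)
        sched = build_phase_schedule(Phase.DP, 2, 90.0)
        acts = distractor_schedule(sched, seed=5)
        scores = {}
        for prof in (ADHD_PROFILE, HC_PROFILE):
            vals = []
            for seed in range(4):
                track = simulate_attention(prof, sched, acts, seed=seed)
                occ = track.occupancy()
                task = occ.get("on_task", 0.0)
                vals.append((occ.get("distracted", 0.0)
                             + occ.get("wandering", 0.0)) / task)
            scores[prof.group] = np.mean(vals)
        assert scores["ADHD"] > scores["HC"]
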