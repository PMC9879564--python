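"""Closed-loop synthetic participant and session generator.

The generative model is a semi-Markov attention process with exponential
holding times over the latent states *on_task*, *distracted*, *wandering*
(plus overlaid *blink* episodes):

* From *on_task*, the participant leaves toward a distractor with rate
  ``distraction_hazard`` (only while a distractor event is animating) or
  into mind wandering with rate ``wander_hazard`` (mildly elevated during
  distractor phases).
* *Distracted* episodes end by disengagement (rate ``refocus_hazard *
  distractor_disengage``) or when the distractor animation ends.
* *Wandering* episodes end with rate ``refocus_hazard``.
* Active gaze-contingent feedback multiplies the refocus rate by
  ``feedback_refocus_boost`` (default 1: no effect is claimed, the knob
  exists to test the mechanism).

The latent track drives every rendered stream: binocular gaze (fixation
jitter, saccadic relocations, blinks as invalid samples), CPT keypresses
(log-normal reaction times while on task, state-dependent omission and
commission probabilities), EEG (1/f background plus theta and beta
oscillations whose theta amplitude is slightly raised during distractor
phases), and head position (a mean-reverting random walk scaled by group).
Feedback events are produced by running the real controller on the rendered
gaze-state stream.

Default profiles for the ADHD and healthy-control groups are calibrated so
that simulated 18+18 cohorts approximate the reference group means this
paradigm produces (per-block omissions ~2.8 vs ~0.9, reaction times
~471 vs ~436 ms, distractor dwell ~1.9% vs ~0.8%, head movement roughly
twice as large in the ADHD group); see docs/methods.md.

Ground-truth labels (latent intervals, true relocation/saccade times,
injected data loss) are returned alongside the streams so every analysis
stage can be tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import cpt as cpt_mod
from .feedback import FeedbackConfig, run_controller
from .oculomotor import BinocularTrace, MonocularTrace
from .scene import (
    DEFAULT_DISTRACTOR_LINGER,
    DistractorActivation,
    GazeState,
    Scene,
    apply_schedule_to_scene,
    classify_gaze_stream,
    default_scene,
    distractor_schedule,
)
from .session import (
    CONDITIONS,
    BlockRecord,
    Condition,
    EEG_CHANNELS,
    Phase,
    PhaseSchedule,
    SessionRecord,
    TimeSeriesStream,
    build_phase_schedule,
)

__all__ = [
    "ParticipantProfile",
    "ADHD_PROFILE",
    "HC_PROFILE",
    "LatentAttentionTrack",
    "GroundTruth",
    "simulate_attention",
    "render_gaze",
    "render_fixation_sequence",
    "simulate_block",
    "simulate_session",
    "simulate_cohort",
]

GAZE_RATE = 50.0
HEAD_RATE = 90.0
EEG_RATE = 500.0

ON_TASK = "on_task"
DISTRACTED = "distracted"
WANDERING = "wandering"
BLINK = "blink"


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one synthetic participant.

    Hazards are rates in 1/s; amplitudes in µV; head steps in meters.
    """

    group: str
    distraction_hazard: float     # toward an animating distractor
    wander_hazard: float          # toward mind wandering
    refocus_hazard: float         # back to task
    distractor_disengage: float   # multiplier on refocus while distracted
    dp_wander_boost: float        # wander-hazard multiplier during DP
    feedback_refocus_boost: float
    rt_median: float              # ms
    rt_sigma: float               # log-scale SD
    omission_prob_ontask: float
    omission_prob_offtask: float
    commission_prob: float
    theta_amp: float
    beta_amp: float
    theta_dp_gain: float          # theta amplitude multiplier during DP
    head_step_sigma: float        # m per 90 Hz step
    blink_rate: float             # 1/s
    es_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    recognition_accuracy: float = 0.7

    def __post_init__(self) -> None:
        for name in ("distraction_hazard", "wander_hazard", "refocus_hazard",
                     "theta_amp", "beta_amp", "head_step_sigma", "blink_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("omission_prob_ontask", "omission_prob_offtask",
                     "commission_prob", "recognition_accuracy"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


ADHD_PROFILE = ParticipantProfile(
    group="ADHD",
    distraction_hazard=0.50,
    wander_hazard=0.050,
    refocus_hazard=0.50,
    distractor_disengage=1.0,
    dp_wander_boost=1.3,
    feedback_refocus_boost=1.0,
    rt_median=458.0,
    rt_sigma=0.18,
    omission_prob_ontask=0.004,
    omission_prob_offtask=0.075,
    commission_prob=0.0019,
    theta_amp=4.0,
    beta_amp=4.0,
    theta_dp_gain=1.012,
    head_step_sigma=3.9e-4,
    blink_rate=0.155,
    es_bias=(1.2, 0.8, 0.5),
    recognition_accuracy=0.70,
)

HC_PROFILE = ParticipantProfile(
    group="HC",
    distraction_hazard=0.30,
    wander_hazard=0.024,
    refocus_hazard=0.50,
    distractor_disengage=2.2,
    dp_wander_boost=1.3,
    feedback_refocus_boost=1.0,
    rt_median=428.0,
    rt_sigma=0.18,
    omission_prob_ontask=0.002,
    omission_prob_offtask=0.025,
    commission_prob=0.0014,
    theta_amp=4.0,
    beta_amp=4.0,
    theta_dp_gain=1.012,
    head_step_sigma=1.7e-4,
    blink_rate=0.155,
    es_bias=(-2.2, -2.4, -2.4),
    recognition_accuracy=0.73,
)


@dataclass(frozen=True)
class LatentInterval:
    state: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class LatentAttentionTrack:
    intervals: list[LatentInterval]

    def __post_init__(self) -> None:
        prev = None
        for iv in self.intervals:
            if iv.end <= iv.start:
                raise ValueError(f"empty latent interval {iv}")
            if prev is not None and abs(iv.start - prev.end) > 1e-9:
                raise ValueError("latent intervals must be contiguous")
            prev = iv

    @property
    def duration(self) -> float:
        return self.intervals[-1].end - self.intervals[0].start

    def state_at(self, t: float) -> str:
        for iv in self.intervals:
            if iv.start <= t < iv.end:
                return iv.state
        return self.intervals[-1].state

    def states_at(self, times: np.ndarray) -> np.ndarray:
        starts = np.array([iv.start for iv in self.intervals])
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1,
                      0, len(self.intervals) - 1)
        labels = np.array([iv.state for iv in self.intervals])
        return labels[idx]

    def occupancy(self) -> dict[str, float]:
        tot: dict[str, float] = {}
        for iv in self.intervals:
            tot[iv.state] = tot.get(iv.state, 0.0) + iv.duration
        d = self.duration
        return {k: v / d for k, v in tot.items()}


def _merge_windows(windows: list[tuple[float, float]]
                   ) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(windows):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _in_windows(t: float, windows: list[tuple[float, float]]) -> bool:
    return any(a <= t < b for a, b in windows)


def _window_end(t: float, windows: list[tuple[float, float]]) -> float:
    for a, b in windows:
        if a <= t < b:
            return b
    return t


def _piecewise_exponential(rng: np.random.Generator, mu: float, boost: float,
                           delay: float, boost_len: float) -> float:
    """Episode duration under rate mu, boosted to mu*boost on
    [delay, delay+boost_len) — the approximate feedback coupling."""
    t1 = rng.exponential(1.0 / mu)
    if boost == 1.0 or t1 <= delay:
        return t1
    t2 = rng.exponential(1.0 / (mu * boost))
    if t2 <= boost_len:
        return delay + t2
    return delay + boost_len + rng.exponential(1.0 / mu)


def simulate_attention(
    profile: ParticipantProfile,
    schedule: PhaseSchedule,
    activations: Sequence[DistractorActivation],
    seed: Optional[int] = None,
    feedback_mode: str = "none",
    feedback_config: FeedbackConfig | None = None,
    distractor_linger: float = DEFAULT_DISTRACTOR_LINGER,
) -> LatentAttentionTrack:
    """Generate the latent semi-Markov attention track for one block.

    Distractor onsets gate the distraction hazard (it is non-zero only while
    a distractor animates); active feedback multiplies the refocus hazard
    (approximated as a boost window opening at the controller's trigger
    latency after the episode start, for ``feedback_refocus_boost != 1``).
    Blink episodes are overlaid as a Poisson process.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    cfg = feedback_config or FeedbackConfig(mode="real")
    t0, t_end = schedule.start, schedule.end
    dist_windows = _merge_windows([
        (a.onset, a.onset + distractor_linger) for a in activations])
    dp_windows = schedule.windows(Phase.DP)
    boost = profile.feedback_refocus_boost if feedback_mode == "real" else 1.0

    intervals: list[LatentInterval] = []
    t = t0
    state = ON_TASK
    while t < t_end - 1e-12:
        if state == ON_TASK:
            lam_w_max = profile.wander_hazard * max(1.0, profile.dp_wander_boost)
            lam_max = lam_w_max + profile.distraction_hazard
            cur = t
            nxt = None
            while True:
                cur += rng.exponential(1.0 / lam_max)
                if cur >= t_end:
                    break
                lam_w = profile.wander_hazard * (
                    profile.dp_wander_boost if _in_windows(cur, dp_windows)
                    else 1.0)
                lam_d = (profile.distraction_hazard
                         if _in_windows(cur, dist_windows) else 0.0)
                if rng.uniform() < (lam_w + lam_d) / lam_max:
                    nxt = DISTRACTED if rng.uniform() < lam_d / (lam_w + lam_d) \
                        else WANDERING
                    break
            end = min(cur, t_end)
            if end > t:
                intervals.append(LatentInterval(ON_TASK, t, end))
            t = end
            state = nxt if nxt is not None else ON_TASK
        elif state == DISTRACTED:
            mu = profile.refocus_hazard * profile.distractor_disengage
            dur = _piecewise_exponential(
                rng, mu, boost, cfg.distractor_threshold, cfg.max_duration)
            end = min(t + dur, _window_end(t, dist_windows), t_end)
            end = max(end, min(t + 1e-3, t_end))
            if end > t:
                intervals.append(LatentInterval(DISTRACTED, t, end))
            t = end
            state = WANDERING if rng.uniform() < 0.15 else ON_TASK
        else:  # WANDERING
            dur = _piecewise_exponential(
                rng, profile.refocus_hazard, boost,
                cfg.off_canvas_threshold, cfg.max_duration)
            end = min(t + dur, t_end)
            if end > t:
                intervals.append(LatentInterval(WANDERING, t, end))
            t = end
            state = ON_TASK

    intervals = _overlay_blinks(intervals, profile, rng, t0, t_end)
    return LatentAttentionTrack(intervals)


def _overlay_blinks(intervals: list[LatentInterval],
                    profile: ParticipantProfile, rng: np.random.Generator,
                    t0: float, t_end: float) -> list[LatentInterval]:
    n = rng.poisson(profile.blink_rate * (t_end - t0))
    onsets = np.sort(rng.uniform(t0, t_end, size=n))
    blinks: list[tuple[float, float]] = []
    for on in onsets:
        dur = min(0.12 + rng.exponential(0.05), 0.4)
        blinks.append((float(on), float(min(on + dur, t_end))))
    blinks = _merge_windows(blinks)
    out: list[LatentInterval] = []
    for iv in intervals:
        cur = iv.start
        for a, b in blinks:
            if b <= cur or a >= iv.end:
                continue
            if a > cur:
                out.append(LatentInterval(iv.state, cur, a))
            out.append(LatentInterval(BLINK, max(a, cur), min(b, iv.end)))
            cur = min(b, iv.end)
        if cur < iv.end:
            out.append(LatentInterval(iv.state, cur, iv.end))
    return out


@dataclass
class GroundTruth:
    track: LatentAttentionTrack
    activations: list[DistractorActivation]
    saccade_times: np.ndarray
    injected_loss_pct: float


# ---------------------------------------------------------------------------
# Gaze rendering
# ---------------------------------------------------------------------------

EYE_ORIGIN = np.array([0.0, 1.2, 0.0])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter_dirs(rng: np.random.Generator, base: np.ndarray, n: int,
                 noise_deg: float) -> np.ndarray:
    d = np.tile(base, (n, 1))
    d = d + rng.normal(0.0, np.deg2rad(noise_deg), size=(n, 3))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _canvas_point(rng: np.random.Generator, scene: Scene) -> np.ndarray:
    c = scene.canvas
    p = c.center + rng.uniform(-0.75, 0.75, 3) * c.extent
    p[2] = c.center[2] - c.extent[2]
    return p


def _wander_direction(rng: np.random.Generator) -> np.ndarray:
    # upward cone (30-60 deg elevation): misses canvas and all distractors
    az = rng.uniform(-np.pi, np.pi)
    el = np.deg2rad(rng.uniform(30.0, 60.0))
    return np.array([np.cos(el) * np.sin(az), np.sin(el),
                     np.cos(el) * np.cos(az)])


def render_gaze(
    track: LatentAttentionTrack,
    scene: Scene,
    activations: Sequence[DistractorActivation],
    seed: Optional[int] = None,
    rate: float = GAZE_RATE,
    noise_deg: float = 0.10,
    relocation_rate: float = 1.2,
    distractor_linger: float = DEFAULT_DISTRACTOR_LINGER,
) -> tuple[BinocularTrace, np.ndarray]:
    """Render the latent track into a ~50 Hz binocular direction trace.

    On-task samples fixate jittered canvas points with Poisson relocations
    (each a ground-truth saccade); distracted samples fixate the animating
    distractor's collider; wandering samples point into an upward cone that
    intersects no collider; blinks are invalid.  Returns the trace and the
    ground-truth saccade (relocation) times.
    """
    rng = np.random.default_rng(seed)
    t0 = track.intervals[0].start
    t_end = track.intervals[-1].end
    n = int(np.floor((t_end - t0) * rate))
    t = t0 + np.arange(n) / rate
    dirs = np.zeros((n, 3))
    valid = np.ones(n, dtype=bool)
    saccade_times: list[float] = []

    act_by_time = sorted(activations, key=lambda a: a.onset)

    def active_target(ts: float) -> np.ndarray:
        past = [a for a in act_by_time if a.onset <= ts]
        if past:
            return scene.collider(past[-1].object_id).center
        if act_by_time:
            return scene.collider(act_by_time[0].object_id).center
        return scene.canvas.center

    prev_target: Optional[np.ndarray] = None
    for iv in track.intervals:
        m = (t >= iv.start - 1e-12) & (t < iv.end - 1e-12)
        idx = np.nonzero(m)[0]
        if iv.state == BLINK:
            if idx.size:
                valid[idx] = False
                dirs[idx] = prev_target if prev_target is not None else \
                    _unit(scene.canvas.center - EYE_ORIGIN)
            continue
        # fixation sub-segments with Poisson relocations
        seg_starts = [iv.start]
        cur = iv.start
        if iv.state in (ON_TASK, WANDERING):
            while True:
                cur += rng.exponential(1.0 / relocation_rate)
                if cur >= iv.end:
                    break
                seg_starts.append(cur)
        seg_bounds = seg_starts + [iv.end]
        for k in range(len(seg_starts)):
            a, b = seg_bounds[k], seg_bounds[k + 1]
            if iv.state == ON_TASK:
                target = _unit(_canvas_point(rng, scene) - EYE_ORIGIN)
            elif iv.state == DISTRACTED:
                target = _unit(active_target(a) - EYE_ORIGIN)
            else:
                target = _wander_direction(rng)
            if idx.size:
                sm = idx[(t[idx] >= a - 1e-12) & (t[idx] < b - 1e-12)]
                if sm.size:
                    dirs[sm] = _jitter_dirs(rng, target, sm.size, noise_deg)
            if prev_target is not None:
                amp = np.degrees(np.arccos(np.clip(
                    np.dot(prev_target, target), -1, 1)))
                if amp > 1.0:
                    saccade_times.append(a)
            prev_target = target

    # binocular: shared direction with tiny independent per-eye noise
    left = dirs + rng.normal(0, np.deg2rad(0.05), dirs.shape)
    right = dirs + rng.normal(0, np.deg2rad(0.05), dirs.shape)
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    trace = BinocularTrace(t=t, left=left, right=right,
                           valid_left=valid.copy(), valid_right=valid.copy())
    return trace, np.asarray(saccade_times)


def render_fixation_sequence(
    fixation_durations: Sequence[float],
    gap_durations: Sequence[float],
    seed: Optional[int] = None,
    rate: float = GAZE_RATE,
    noise_deg: float = 0.10,
    amplitude_deg: tuple[float, float] = (4.0, 15.0),
    same_location_gaps: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled fixation/saccade trace for detector testing.

    Builds ``len(fixation_durations)`` fixations separated by high-velocity
    gaps of the given durations.  With ``same_location_gaps`` the gaze
    returns to the previous fixation direction after each gap (an
    out-and-back excursion), the stimulus for the merge rule; otherwise each
    gap is a saccade to a new location with amplitude drawn from
    ``amplitude_deg``.

    Returns ``(t, directions, fixation_bounds)`` where ``fixation_bounds``
    is an ``(n_fix, 2)`` array of ground-truth [start, end] times.
    """
    if len(gap_durations) != len(fixation_durations) - 1:
        raise ValueError("need exactly n_fixations - 1 gaps")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    dirs: list[np.ndarray] = []
    bounds = []
    base = _unit(np.array([0.0, 0.0, 1.0]))
    t_cursor = 0.0
    for i, fd in enumerate(fixation_durations):
        n_fix = max(1, int(round(fd * rate)))
        dirs.extend(_jitter_dirs(rng, base, n_fix, noise_deg))
        bounds.append((t_cursor, t_cursor + (n_fix - 1) * dt))
        t_cursor += n_fix * dt
        if i < len(gap_durations):
            n_gap = max(1, int(round(gap_durations[i] * rate)))
            amp = np.deg2rad(rng.uniform(*amplitude_deg))
            next_base = base
            if not same_location_gaps:
                amp2 = np.deg2rad(rng.uniform(*amplitude_deg))
                next_base = _unit(base + amp2 * _unit(rng.normal(size=3)))
            # oscillate between two far points straddling the path so every
            # consecutive gap sample moves at clearly saccadic velocity
            mid = _unit(base + next_base)
            ortho = rng.normal(size=3)
            ortho -= mid * np.dot(ortho, mid)
            ortho = _unit(ortho)
            for k in range(n_gap):
                sign = 1.0 if k % 2 == 0 else -1.0
                dirs.append(_unit(mid + sign * amp * ortho))
            t_cursor += n_gap * dt
            base = next_base
    d = np.asarray(dirs)
    t = np.arange(len(d)) * dt
    return t, d, np.asarray(bounds)


# ---------------------------------------------------------------------------
# Stream rendering: responses, EEG, head
# ---------------------------------------------------------------------------

def simulate_responses(
    track: LatentAttentionTrack,
    block: "cpt_mod.CPTBlock",
    profile: ParticipantProfile,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Keypress times: state-dependent omissions/commissions, log-normal RTs."""
    rng = np.random.default_rng(seed)
    responses = []
    for trial in block.trials:
        state = track.state_at(trial.onset + 0.2)
        on = state in (ON_TASK, BLINK)
        if trial.trial_class == cpt_mod.TrialClass.TARGET:
            p_omit = (profile.omission_prob_ontask if on
                      else profile.omission_prob_offtask)
            if rng.uniform() >= p_omit:
                rt = rng.lognormal(np.log(profile.rt_median / 1000.0),
                                   profile.rt_sigma)
                if not on:
                    rt *= 1.15  # sluggish recovery responses
                rt = float(np.clip(rt, 0.15, block.soa - 0.01))
                responses.append(trial.onset + rt)
        else:
            if rng.uniform() < profile.commission_prob:
                rt = float(np.clip(rng.lognormal(
                    np.log(profile.rt_median / 1000.0), profile.rt_sigma),
                    0.15, block.soa - 0.01))
                responses.append(trial.onset + rt)
    return np.asarray(sorted(responses))


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                sigma: float) -> np.ndarray:
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return sigma * x / x.std()


def simulate_eeg(
    profile: ParticipantProfile,
    schedule: PhaseSchedule,
    seed: Optional[int] = None,
    fs: float = EEG_RATE,
    background_sigma: float = 8.0,
    artifact_rate: float = 0.01,
) -> TimeSeriesStream:
    """24-channel EEG: 1/f background + theta/beta oscillations (µV).

    Theta amplitude is multiplied by ``theta_dp_gain`` during distractor
    phases.  Occasional large-amplitude spikes exercise epoch rejection.
    """
    rng = np.random.default_rng(seed)
    n = int(np.floor(schedule.duration * fs))
    t = schedule.start + np.arange(n) / fs
    dp_gain = np.ones(n)
    for a, b in schedule.windows(Phase.DP):
        dp_gain[(t >= a) & (t < b)] = profile.theta_dp_gain
    values = np.empty((n, len(EEG_CHANNELS)))
    for ci in range(len(EEG_CHANNELS)):
        phase_t = rng.uniform(0, 2 * np.pi)
        phase_b = rng.uniform(0, 2 * np.pi)
        x = _pink_noise(rng, n, fs, background_sigma)
        x += profile.theta_amp * dp_gain * np.sin(2 * np.pi * 5.5 * t + phase_t)
        x += profile.beta_amp * np.sin(2 * np.pi * 18.5 * t + phase_b)
        values[:, ci] = x
    n_art = rng.poisson(artifact_rate * schedule.duration)
    for _ in range(n_art):
        i0 = int(rng.integers(0, max(1, n - 50)))
        values[i0:i0 + 50, :] += rng.choice([-1.0, 1.0]) * 400.0
    return TimeSeriesStream(name="eeg", nominal_rate=fs,
                            channels=EEG_CHANNELS, timestamps=t, values=values)


def simulate_head(
    profile: ParticipantProfile,
    duration: float,
    seed: Optional[int] = None,
    fs: float = HEAD_RATE,
    start: float = 0.0,
) -> TimeSeriesStream:
    """Mean-reverting 3D random walk of the HMD position (meters)."""
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration * fs))
    t = start + np.arange(n) / fs
    steps = rng.normal(0.0, profile.head_step_sigma, size=(n, 3))
    pos = np.empty((n, 3))
    anchor = np.array([0.0, 1.35, -0.1])
    pos[0] = anchor
    rho = 0.995
    for i in range(1, n):
        pos[i] = anchor + rho * (pos[i - 1] - anchor) + steps[i]
    return TimeSeriesStream(name="head", nominal_rate=fs,
                            channels=("x", "y", "z"), timestamps=t, values=pos)


# ---------------------------------------------------------------------------
# Block / session / cohort assembly
# ---------------------------------------------------------------------------

def simulate_block(
    profile: ParticipantProfile,
    condition: Condition | str,
    seed: int,
    schedule: Optional[PhaseSchedule] = None,
    scene: Optional[Scene] = None,
    include_eeg: bool = True,
    start_phase: Phase = Phase.DP,
    n_phases: int = 6,
    phase_seconds: float = 180.0,
) -> tuple[BlockRecord, GroundTruth]:
    """Simulate one full block under the given feedback condition."""
    condition = Condition(condition)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]
    if schedule is None:
        schedule = build_phase_schedule(start_phase, n_phases, phase_seconds)
    scene = scene if scene is not None else default_scene()
    activations = distractor_schedule(schedule, seed=sub[0])
    apply_schedule_to_scene(scene, activations)

    track = simulate_attention(
        profile, schedule, activations, seed=sub[1],
        feedback_mode=condition.value,
    )
    trace, saccade_times = render_gaze(track, scene, activations, seed=sub[2])

    # classify the rendered rays and run the online controller on them
    n = len(trace.t)
    origins = np.tile(EYE_ORIGIN, (n, 1))
    cyc = trace.left + trace.right
    cyc /= np.linalg.norm(cyc, axis=1, keepdims=True)
    states, _ = classify_gaze_stream(trace.t, origins, cyc, scene,
                                     valid=trace.valid_left | trace.valid_right)
    fb_config = FeedbackConfig(mode=condition.value, seed=sub[3])
    feedback_events = run_controller(trace.t, states, fb_config)

    block = cpt_mod.generate_cpt_block(
        seed=sub[4],
        n_trials=int(round(schedule.duration /
                           (cpt_mod.DEFAULT_STIMULUS_DURATION
                            + cpt_mod.DEFAULT_ISI))),
    )
    responses = simulate_responses(track, block, profile, seed=sub[5])
    head = simulate_head(profile, schedule.duration, seed=sub[6],
                         start=schedule.start)
    eeg = simulate_eeg(profile, schedule, seed=sub[7]) if include_eeg else None

    gaze_vals = np.hstack([
        np.tile(EYE_ORIGIN, (n, 1)), trace.left,
        trace.valid_left[:, None].astype(float),
        np.tile(EYE_ORIGIN, (n, 1)), trace.right,
        trace.valid_right[:, None].astype(float),
    ])
    gaze = TimeSeriesStream(
        name="gaze", nominal_rate=GAZE_RATE,
        channels=("lx", "ly", "lz", "ldx", "ldy", "ldz", "validity_l",
                  "rx", "ry", "rz", "rdx", "rdy", "rdz", "validity_r"),
        timestamps=trace.t, values=gaze_vals,
        validity=trace.valid_left | trace.valid_right,
    )
    es_rng = np.random.default_rng(sub[5] + 1)
    es = {
        k: int(np.clip(round(b + es_rng.normal(0, 0.8)), -3, 3))
        for k, b in zip(("inattention", "hyperactivity", "impulsivity"),
                        profile.es_bias)
    }
    record = BlockRecord(
        condition=condition, phase_schedule=schedule, gaze=gaze, head=head,
        eeg=eeg, cpt_block=block, responses=responses,
        feedback_events=feedback_events, experience_sampling=es,
    )
    occ = track.occupancy()
    truth = GroundTruth(
        track=track, activations=list(activations),
        saccade_times=saccade_times,
        injected_loss_pct=100.0 * occ.get(BLINK, 0.0),
    )
    return record, truth


def simulate_session(
    participant_id: str,
    group: str,
    seed: int,
    condition_order: Optional[Sequence[Condition | str]] = None,
    profile: Optional[ParticipantProfile] = None,
    include_eeg: bool = False,
    start_phase: Phase = Phase.DP,
    n_phases: int = 6,
    phase_seconds: float = 180.0,
    scene: Optional[Scene] = None,
) -> tuple[SessionRecord, list[GroundTruth]]:
    """Simulate the three counterbalanced blocks of one participant."""
    if profile is None:
        profile = ADHD_PROFILE if group == "ADHD" else HC_PROFILE
    if condition_order is None:
        condition_order = CONDITIONS
    condition_order = tuple(Condition(c) for c in condition_order)
    rng = np.random.default_rng(seed)
    blocks, truths = [], []
    for cond in condition_order:
        rec, tr = simulate_block(
            profile, cond, seed=int(rng.integers(0, 2**31 - 1)),
            include_eeg=include_eeg, start_phase=start_phase,
            n_phases=n_phases, phase_seconds=phase_seconds, scene=scene,
        )
        blocks.append(rec)
        truths.append(tr)
    n_rec = 60
    truth_rec = np.arange(n_rec) < n_rec // 2
    rng.shuffle(truth_rec)
    correct = rng.uniform(size=n_rec) < profile.recognition_accuracy
    responses_rec = np.where(correct, truth_rec, ~truth_rec)
    session = SessionRecord(
        participant_id=participant_id, group=group,
        condition_order=condition_order, blocks=blocks,
        recognition_responses=responses_rec, recognition_truth=truth_rec,
    )
    return session, truths


def simulate_cohort(
    n_adhd: int = 18,
    n_hc: int = 18,
    seed: int = 0,
    **session_kwargs,
) -> list[SessionRecord]:
    """Simulate a two-group cohort with counterbalanced condition orders."""
    import itertools

    orders = list(itertools.permutations(CONDITIONS))
    rng = np.random.default_rng(seed)
    sessions = []
    i = 0
    for group, n in (("ADHD", n_adhd), ("HC", n_hc)):
        for k in range(n):
            s, _ = simulate_session(
                participant_id=f"{group.lower()}{k:02d}", group=group,
                seed=int(rng.integers(0, 2**31 - 1)),
                condition_order=orders[i % len(orders)],
                start_phase=Phase.DP if i % 2 == 0 else Phase.NDP,
                **session_kwargs,
            )
            sessions.append(s)
            i += 1
    return sessions
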