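"""Gaze-contingent feedback controller (real, sham, and no-feedback policy).

The controller consumes the 50 Hz gaze-state stream and accumulates two dwell
timers: an *off-canvas* timer that runs whenever the gaze is not on the task
canvas, and a *distractor* timer that runs only while a distractor is
fixated.  An inattention registration occurs at the first sample at which a
timer strictly exceeds its threshold (2 s off-canvas, 0.5 s on-distractor).

* ``real`` mode fires immediately at registration (unless an event is active
  or the 5 s refractory period is running, in which case it fires at the
  first admissible sample while the gaze stays away).
* ``sham`` mode schedules the event at registration + U(20, 30) s and fires
  at that time regardless of the momentary gaze state; at most one sham is
  pending at a time.
* ``none`` mode never emits.

An active event ends at the first task-focus sample or after 2 s, whichever
comes first; its visual envelope fades linearly to 35% screen coverage over
0.5 s.  After the offset, a 5 s refractory period starts and both timers
restart from zero.  Invalid (blink) samples freeze the timers: blinks neither
count as inattention nor restore task focus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .scene import GazeState

__all__ = [
    "FeedbackConfig",
    "FeedbackEvent",
    "ControllerState",
    "step_controller",
    "run_controller",
    "feedback_envelope",
    "read_feedback_csv",
    "write_feedback_csv",
]

MAX_ENVELOPE = 0.35


@dataclass(frozen=True)
class FeedbackConfig:
    mode: str = "real"  # "real" | "sham" | "none"
    off_canvas_threshold: float = 2.0
    distractor_threshold: float = 0.5
    refractory: float = 5.0
    max_duration: float = 2.0
    fade_in: float = 0.5
    sham_delay_range: tuple[float, float] = (20.0, 30.0)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("real", "sham", "none"):
            raise ValueError(f"unknown feedback mode {self.mode!r}")
        for name in ("off_canvas_threshold", "distractor_threshold",
                     "refractory", "max_duration", "fade_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.sham_delay_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid sham_delay_range {self.sham_delay_range}")


@dataclass(frozen=True)
class FeedbackEvent:
    onset: float
    offset: float
    cause: str  # "off_canvas" | "distractor" | "sham"
    triggering_registration_time: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"event onset {self.onset} !< offset {self.offset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class ControllerState:
    """Explicit mutable state folded over the gaze-state stream."""

    off_canvas_timer: float = 0.0
    distractor_timer: float = 0.0
    registered: bool = False
    registration_time: float = float("nan")
    registration_cause: str = ""
    active_onset: Optional[float] = None
    active_cause: str = ""
    active_registration: float = float("nan")
    refractory_until: float = -float("inf")
    pending_sham_fire: Optional[float] = None
    pending_sham_registration: float = float("nan")
    last_t: float = -float("inf")


def step_controller(
    state: ControllerState,
    gaze_state: str,
    t: float,
    dt: float,
    config: FeedbackConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[FeedbackEvent]:
    """Advance the controller by one sample; returns completed events.

    ``state`` is mutated in place.  ``t`` must be strictly increasing across
    calls and ``dt`` is the elapsed time attributed to this sample.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t <= state.last_t:
        raise ValueError(f"non-monotonic controller time: {state.last_t} -> {t}")
    state.last_t = t
    emitted: list[FeedbackEvent] = []

    # --- terminate an active event -------------------------------------
    if state.active_onset is not None:
        offset = None
        if t - state.active_onset >= config.max_duration:
            offset = state.active_onset + config.max_duration
        elif gaze_state == GazeState.TASK_FOCUS:
            offset = t
        if offset is not None:
            emitted.append(FeedbackEvent(
                onset=state.active_onset, offset=offset,
                cause=state.active_cause,
                triggering_registration_time=state.active_registration,
            ))
            state.active_onset = None
            state.refractory_until = offset + config.refractory
            _reset_timers(state)

    # --- timer accumulation (frozen during an active event and blinks) --
    if state.active_onset is None:
        if gaze_state == GazeState.TASK_FOCUS:
            _reset_timers(state)
        elif gaze_state == GazeState.INVALID:
            pass  # freeze: blinks neither accumulate nor reset
        else:
            state.off_canvas_timer += dt
            if gaze_state == GazeState.DISTRACTOR_FOCUS:
                state.distractor_timer += dt
            else:
                state.distractor_timer = 0.0

        # --- registration edge ------------------------------------------
        if not state.registered:
            cause = None
            if state.distractor_timer > config.distractor_threshold:
                cause = "distractor"
            elif state.off_canvas_timer > config.off_canvas_threshold:
                cause = "off_canvas"
            if cause is not None:
                state.registered = True
                state.registration_time = t
                state.registration_cause = cause
                if config.mode == "sham" and state.pending_sham_fire is None:
                    if rng is None:
                        raise ValueError("sham mode requires an rng")
                    delay = rng.uniform(*config.sham_delay_range)
                    state.pending_sham_fire = t + delay
                    state.pending_sham_registration = t

        # --- firing -------------------------------------------------------
        can_fire = t >= state.refractory_until
        if config.mode == "real" and state.registered and can_fire:
            state.active_onset = t
            state.active_cause = state.registration_cause
            state.active_registration = state.registration_time
        elif (config.mode == "sham" and state.pending_sham_fire is not None
              and t >= state.pending_sham_fire and can_fire):
            state.active_onset = t
            state.active_cause = "sham"
            state.active_registration = state.pending_sham_registration
            state.pending_sham_fire = None

    return emitted


def _reset_timers(state: ControllerState) -> None:
    state.off_canvas_timer = 0.0
    state.distractor_timer = 0.0
    state.registered = False


def run_controller(
    timestamps: Sequence[float] | np.ndarray,
    gaze_states: Sequence[str],
    config: FeedbackConfig,
) -> list[FeedbackEvent]:
    """Fold :func:`step_controller` over an ordered gaze-state stream.

    Deterministic for real/none; reproducible per ``config.seed`` for sham.
    A still-active event at stream end is closed at the final timestamp.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != len(gaze_states):
        raise ValueError("timestamps and gaze_states must have equal length")
    if config.mode == "none":
        return []
    rng = np.random.default_rng(config.seed)
    state = ControllerState()
    events: list[FeedbackEvent] = []
    prev_t = None
    for i, t in enumerate(timestamps):
        dt = (t - prev_t) if prev_t is not None else (
            timestamps[1] - timestamps[0] if len(timestamps) > 1 else 0.02)
        prev_t = t
        events.extend(step_controller(
            state, gaze_states[i], float(t), float(dt), config, rng))
    if state.active_onset is not None:
        end = min(float(timestamps[-1]) + 1e-9,
                  state.active_onset + config.max_duration)
        events.append(FeedbackEvent(
            onset=state.active_onset, offset=end, cause=state.active_cause,
            triggering_registration_time=state.active_registration,
        ))
    return events


def feedback_envelope(event: FeedbackEvent, t: float,
                      config: FeedbackConfig = FeedbackConfig()) -> float:
    """Black-overlay opacity fraction at time ``t``: linear 0 -> 0.35 ramp
    over ``fade_in`` seconds, then constant; 0 outside the event."""
    if t < event.onset or t > event.offset:
        return 0.0
    return min(MAX_ENVELOPE, MAX_ENVELOPE * (t - event.onset) / config.fade_in)


def write_feedback_csv(events: Iterable[FeedbackEvent], mode: str,
                       path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset", "offset", "cause", "mode", "registration"])
        for e in events:
            w.writerow([repr(e.onset), repr(e.offset), e.cause, mode,
                        repr(e.triggering_registration_time)])


def read_feedback_csv(path: str | Path) -> list[FeedbackEvent]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(FeedbackEvent(
                onset=float(row["onset"]), offset=float(row["offset"]),
                cause=row["cause"],
                triggering_registration_time=float(
                    row.get("registration", row["onset"])),
            ))
    return out
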