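"""Offline eye-movement preprocessing and velocity-based event detection.

The pipeline mirrors a standard adaptive, data-driven saccade detector for
~50 Hz head-mounted eye tracking:

1. **Preprocessing** — per-eye linear interpolation across validity gaps of at
   most 75 ms (on direction components, renormalized), compensation of
   one-eye loss from the other eye, binocular averaging, and a report of the
   residual data loss.
2. **Velocity** — sample-to-sample angular velocity (deg/s) from consecutive
   direction vectors, smoothed with a second-order Savitzky-Golay FIR filter;
   acceleration as the first difference of the smoothed velocity.
3. **Adaptive threshold** — iterative scheme starting at 100 deg/s; each
   iteration sets the threshold to mean + 6 SD of the sub-threshold samples
   until the change falls below 1 deg/s.
4. **Events** — supra-threshold runs are saccades (onset/offset refined to
   the adjacent velocity minima); the spans between them are fixation
   candidates.  Fixations shorter than 60 ms are discarded, and fixations
   separated by gaps of at most 40 ms are merged (saccades swallowed by a
   merge are dropped so events never overlap).

Velocities are angular and head-relative: they are computed from gaze
direction vectors only, ignoring origin motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .session import Phase, PhaseSchedule

__all__ = [
    "DetectorParams",
    "BinocularTrace",
    "MonocularTrace",
    "VelocityTrace",
    "SaccadeEvent",
    "FixationEvent",
    "preprocess",
    "compute_velocity",
    "adaptive_threshold",
    "detect_events",
    "summarize_saccades",
]


@dataclass(frozen=True)
class DetectorParams:
    sg_order: int = 2
    sg_window: int = 5              # samples (~100 ms at 50 Hz)
    max_gap_interp: float = 0.075   # s
    min_fixation: float = 0.060     # s
    merge_interval: float = 0.040   # s
    threshold_multiplier: float = 6.0
    threshold_init: float = 100.0   # deg/s
    threshold_tol: float = 1.0      # deg/s
    max_threshold_iter: int = 100

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        for name in ("max_gap_interp", "min_fixation", "merge_interval",
                     "threshold_init", "threshold_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class BinocularTrace:
    """Raw binocular gaze directions with per-eye validity (~50 Hz)."""

    t: np.ndarray
    left: np.ndarray    # (n, 3) unit direction vectors
    right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.left = np.asarray(self.left, float)
        self.right = np.asarray(self.right, float)
        self.valid_left = np.asarray(self.valid_left, bool)
        self.valid_right = np.asarray(self.valid_right, bool)
        n = self.t.shape[0]
        for name in ("left", "right", "valid_left", "valid_right"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class MonocularTrace:
    """Cyclopean (averaged) direction trace with residual validity."""

    t: np.ndarray
    direction: np.ndarray
    valid: np.ndarray
    data_loss_pct: float


@dataclass
class VelocityTrace:
    t: np.ndarray
    velocity: np.ndarray       # deg/s, >= 0, SG-smoothed
    acceleration: np.ndarray   # deg/s^2
    raw_velocity: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class SaccadeEvent:
    start: float
    end: float
    amplitude: float      # deg
    peak_velocity: float  # deg/s

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass(frozen=True)
class FixationEvent:
    start: float
    end: float
    centroid: tuple[float, float, float]

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


def _interpolate_gaps(t: np.ndarray, d: np.ndarray, valid: np.ndarray,
                      max_gap: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill invalid runs bounded by valid samples and <= max_gap.

    The gap duration is measured between the flanking valid samples;
    interpolation acts on raw components, renormalized afterwards.
    """
    d = d.copy()
    valid = valid.copy()
    n = len(t)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        if i > 0 and j < n and (t[j] - t[i - 1]) <= max_gap:
            for k in range(i, j):
                w = (t[k] - t[i - 1]) / (t[j] - t[i - 1])
                v = (1 - w) * d[i - 1] + w * d[j]
                nv = np.linalg.norm(v)
                if nv > 1e-9:
                    d[k] = v / nv
                    valid[k] = True
        i = j
    return d, valid


def preprocess(trace: BinocularTrace,
               params: DetectorParams = DetectorParams()) -> MonocularTrace:
    """Fill short gaps per eye, compensate one-eye loss, average both eyes.

    Residual invalid samples (both-eye gaps exceeding ``max_gap_interp``) are
    reported as the data-loss percentage.  An all-invalid trace is an error.
    """
    if not np.any(trace.valid_left | trace.valid_right):
        raise ValueError("trace contains no valid samples in either eye")
    dl, vl = _interpolate_gaps(trace.t, trace.left, trace.valid_left,
                               params.max_gap_interp)
    dr, vr = _interpolate_gaps(trace.t, trace.right, trace.valid_right,
                               params.max_gap_interp)
    n = len(trace.t)
    out = np.zeros((n, 3))
    valid = vl | vr
    both = vl & vr
    out[both] = dl[both] + dr[both]
    only_l = vl & ~vr
    only_r = vr & ~vl
    out[only_l] = dl[only_l]
    out[only_r] = dr[only_r]
    norms = np.linalg.norm(out, axis=1)
    nz = norms > 1e-9
    out[nz] /= norms[nz][:, None]
    valid &= nz
    loss = 100.0 * (1.0 - valid.mean())
    return MonocularTrace(t=trace.t, direction=out, valid=valid,
                          data_loss_pct=float(loss))


def _angles_deg(d: np.ndarray) -> np.ndarray:
    dots = np.clip(np.einsum("ij,ij->i", d[:-1], d[1:]), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def compute_velocity(trace: MonocularTrace,
                     params: DetectorParams = DetectorParams()
                     ) -> VelocityTrace:
    """Angular sample-to-sample velocity, SG-smoothed, plus acceleration.

    The velocity at index i is the angular displacement from sample i-1 to i
    divided by the elapsed time; index 0 repeats index 1 so the trace keeps
    the input length.  Smoothing can undershoot slightly; negative values are
    clipped to zero.
    """
    n = len(trace.t)
    if n < params.sg_window:
        raise ValueError(
            f"trace too short for smoothing: {n} < sg_window={params.sg_window}"
        )
    dt = np.diff(trace.t)
    raw = np.empty(n)
    raw[1:] = _angles_deg(trace.direction) / dt
    raw[0] = raw[1] if n > 1 else 0.0
    # invalid samples contribute no meaningful velocity
    vel_valid = trace.valid.copy()
    vel_valid[1:] &= trace.valid[:-1]
    vel_valid[0] = vel_valid[1] if n > 1 else trace.valid[0]
    raw[~vel_valid] = 0.0
    smooth = savgol_filter(raw, params.sg_window, params.sg_order)
    smooth = np.clip(smooth, 0.0, None)
    accel = np.empty(n)
    accel[1:] = np.diff(smooth) / dt
    accel[0] = accel[1] if n > 1 else 0.0
    return VelocityTrace(t=trace.t, velocity=smooth, acceleration=accel,
                         raw_velocity=raw, valid=vel_valid)


def adaptive_threshold(velocities: np.ndarray,
                       params: DetectorParams = DetectorParams()) -> float:
    """Data-driven peak-velocity threshold.

    Iterates ``PT_{n+1} = mean + multiplier * SD`` over the samples with
    velocity <= PT_n, starting from ``threshold_init``, until successive
    thresholds differ by less than ``threshold_tol`` deg/s.
    """
    v = np.asarray(velocities, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty velocity set")
    pt = params.threshold_init
    for _ in range(params.max_threshold_iter):
        below = v[v <= pt]
        if below.size == 0:
            below = np.array([v.min()])
        new = float(below.mean() + params.threshold_multiplier * below.std())
        if abs(new - pt) < params.threshold_tol:
            return new
        pt = new
    raise RuntimeError(
        f"adaptive threshold did not converge after "
        f"{params.max_threshold_iter} iterations (last PT={pt:.2f} deg/s)"
    )


def _valid_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of valid samples as (start, end) index pairs, inclusive."""
    segs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1]:
            j += 1
        segs.append((i, j))
        i = j + 1
    return segs


def detect_events(
    trace: MonocularTrace,
    params: DetectorParams = DetectorParams(),
    threshold: Optional[float] = None,
) -> tuple[list[SaccadeEvent], list[FixationEvent]]:
    """Detect saccades and fixations on a preprocessed trace.

    Each maximal valid segment is processed independently.  Returns
    time-ordered, non-overlapping event lists satisfying the 60 ms minimum
    fixation duration and the 40 ms merge rule.
    """
    vt = compute_velocity(trace, params)
    if threshold is None:
        # The threshold is estimated on the *raw* sample-to-sample
        # velocities: at ~50 Hz the SG smoothing smears each saccade across
        # several neighbouring samples, and those shoulder velocities would
        # inflate the sub-threshold SD enough to destabilize the iteration.
        vv = vt.raw_velocity[vt.valid]
        threshold = adaptive_threshold(vv, params) if vv.size else np.inf

    saccades: list[SaccadeEvent] = []
    fixations: list[FixationEvent] = []
    for s0, s1 in _valid_segments(vt.valid):
        if s1 - s0 + 1 < 2:
            continue
        sac_idx = _segment_saccades(vt, s0, s1, threshold)
        sacs = []
        for a, b in sac_idx:
            amp = _saccade_amplitude(trace, a, b, s0, s1)
            sacs.append(SaccadeEvent(
                start=float(vt.t[a]), end=float(vt.t[b]),
                amplitude=amp,
                peak_velocity=float(vt.velocity[a:b + 1].max()),
            ))
        fixs = _segment_fixations(trace, sac_idx, s0, s1, params)
        # drop saccades swallowed by a fixation merge
        sacs = [s for s in sacs if not any(
            f.start <= s.start and s.end <= f.end for f in fixs)]
        saccades.extend(sacs)
        fixations.extend(fixs)
    return saccades, fixations


def _segment_saccades(vt: VelocityTrace, s0: int, s1: int, threshold: float
                      ) -> list[tuple[int, int]]:
    v = vt.velocity
    idx = []
    i = s0
    while i <= s1:
        if v[i] > threshold:
            a = i
            while i + 1 <= s1 and v[i + 1] > threshold:
                i += 1
            b = i
            # refine to adjacent local minima
            while a - 1 >= s0 and v[a - 1] < v[a]:
                a -= 1
            while b + 1 <= s1 and v[b + 1] < v[b]:
                b += 1
            if idx and a <= idx[-1][1]:
                idx[-1] = (idx[-1][0], max(idx[-1][1], b))
            else:
                idx.append((a, b))
        i += 1
    return idx


def _saccade_amplitude(trace: MonocularTrace, a: int, b: int,
                       s0: int, s1: int, n_ctx: int = 3) -> float:
    pre = trace.direction[max(s0, a - n_ctx):a]
    post = trace.direction[b + 1:min(s1, b + n_ctx) + 1]
    if len(pre) == 0:
        pre = trace.direction[a:a + 1]
    if len(post) == 0:
        post = trace.direction[b:b + 1]
    u = pre.mean(axis=0)
    w = post.mean(axis=0)
    u /= max(np.linalg.norm(u), 1e-12)
    w /= max(np.linalg.norm(w), 1e-12)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def _segment_fixations(trace: MonocularTrace, sac_idx: list[tuple[int, int]],
                       s0: int, s1: int, params: DetectorParams
                       ) -> list[FixationEvent]:
    spans = []
    prev_end = s0
    for a, b in sac_idx:
        if a > prev_end:
            spans.append((prev_end, a))
        prev_end = b
    if s1 > prev_end:
        spans.append((prev_end, s1))

    def mk(a: int, b: int) -> FixationEvent:
        c = trace.direction[a:b + 1].mean(axis=0)
        c /= max(np.linalg.norm(c), 1e-12)
        return FixationEvent(start=float(trace.t[a]), end=float(trace.t[b]),
                             centroid=(float(c[0]), float(c[1]), float(c[2])))

    candidates = [mk(a, b) for a, b in spans
                  if trace.t[b] - trace.t[a] >= params.min_fixation]
    # merge consecutive fixations separated by <= merge_interval
    merged: list[FixationEvent] = []
    for f in candidates:
        if merged and (f.start - merged[-1].end) <= params.merge_interval:
            prev = merged[-1]
            c = np.add(prev.centroid, f.centroid)
            c /= max(np.linalg.norm(c), 1e-12)
            merged[-1] = FixationEvent(
                start=prev.start, end=f.end,
                centroid=(float(c[0]), float(c[1]), float(c[2])))
        else:
            merged.append(f)
    return merged


def summarize_saccades(
    saccades: Sequence[SaccadeEvent],
    schedule: PhaseSchedule,
) -> dict[Phase, dict[str, float]]:
    """Per-phase-type saccade count and mean duration (ms).

    Events are assigned by onset with half-open phase windows; a phase type
    without events reports count 0 and a missing (NaN) mean duration.
    """
    out = {}
    for phase in (Phase.DP, Phase.NDP):
        durs = [s.duration_ms for s in saccades
                if schedule.phase_at(s.start) == phase]
        out[phase] = {
            "count": float(len(durs)),
            "mean_duration_ms": float(np.mean(durs)) if durs else float("nan"),
        }
    return out
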