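"""Gaze-state classification by ray-collider intersection and dwell analysis.

The virtual scene is reduced to proxy volumes ("colliders"): one canvas box on
which the task is presented, and box or sphere colliders for distractor
events.  Each gaze sample is a ray (origin + unit direction); the nearest
intersected active collider determines the gaze state:

* canvas hit       -> ``task_focus``
* distractor hit   -> ``distractor_focus``
* no hit           -> ``gaze_wandering``
* invalid sample   -> ``invalid`` (blink or tracking loss)

Distractor colliders are only hittable during their activation window (the
scheduled onset plus a configurable linger emulating the animation duration).
Dwell times per state are expressed as percentages of total block duration
(including invalid time), and summarized by the distractibility score

    (distractor-focus % + gaze-wandering %) / task-focus %

where a higher score indicates a higher level of distraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .session import Phase, PhaseSchedule

__all__ = [
    "GazeState",
    "Collider",
    "Scene",
    "GazeStateInterval",
    "DwellSummary",
    "DistractorActivation",
    "distractor_schedule",
    "classify_gaze_sample",
    "classify_gaze_stream",
    "intervals_from_samples",
    "dwell_summary",
    "default_scene",
]

DEFAULT_DISTRACTOR_INTERVAL = 30.0
DEFAULT_DISTRACTOR_LINGER = 3.0
DISTRACTOR_POOL_SIZES = {"visual": 18, "auditory": 18, "audiovisual": 18}


class GazeState:
    TASK_FOCUS = "task_focus"
    DISTRACTOR_FOCUS = "distractor_focus"
    GAZE_WANDERING = "gaze_wandering"
    INVALID = "invalid"

    ALL = (TASK_FOCUS, DISTRACTOR_FOCUS, GAZE_WANDERING, INVALID)


@dataclass
class Collider:
    """Axis-aligned box or sphere proxy volume in scene coordinates (meters).

    ``extent`` holds box half-sizes per axis, or ``(radius, 0, 0)`` for a
    sphere.  ``active_windows`` restricts when a distractor collider is
    hittable; the canvas is always active.
    """

    object_id: str
    kind: str  # "canvas" | "distractor" | "other"
    shape: str  # "box" | "sphere"
    center: np.ndarray
    extent: np.ndarray
    active_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.extent = np.asarray(self.extent, dtype=float)
        if self.shape not in ("box", "sphere"):
            raise ValueError(f"unknown collider shape {self.shape!r}")
        if self.shape == "box" and np.any(self.extent <= 0):
            raise ValueError(f"collider {self.object_id}: extents must be > 0")
        if self.shape == "sphere" and self.extent[0] <= 0:
            raise ValueError(f"collider {self.object_id}: radius must be > 0")

    def active_at(self, t: float) -> bool:
        if self.kind != "distractor":
            return True
        return any(a <= t < b for a, b in self.active_windows)

    def contains(self, p: np.ndarray) -> bool:
        """Point-inclusion test (used by the brute-force oracle in tests)."""
        p = np.asarray(p, dtype=float)
        if self.shape == "sphere":
            return float(np.linalg.norm(p - self.center)) <= self.extent[0]
        return bool(np.all(np.abs(p - self.center) <= self.extent))

    def ray_intersect(self, origin: np.ndarray, direction: np.ndarray
                      ) -> Optional[float]:
        """Smallest non-negative ray parameter hitting the volume, or None."""
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        if self.shape == "sphere":
            oc = o - self.center
            b = float(np.dot(oc, d))
            c = float(np.dot(oc, oc)) - float(self.extent[0]) ** 2
            disc = b * b - c
            if disc < 0:
                return None
            sq = float(np.sqrt(disc))
            t0, t1 = -b - sq, -b + sq
            if t1 < 0:
                return None
            return max(t0, 0.0)
        # Slab method for the axis-aligned box.
        lo = self.center - self.extent
        hi = self.center + self.extent
        tmin, tmax = 0.0, np.inf
        for ax in range(3):
            if d[ax] == 0.0:
                if o[ax] < lo[ax] or o[ax] > hi[ax]:
                    return None
                continue
            t0 = (lo[ax] - o[ax]) / d[ax]
            t1 = (hi[ax] - o[ax]) / d[ax]
            if t0 > t1:
                t0, t1 = t1, t0
            tmin = max(tmin, t0)
            tmax = min(tmax, t1)
            if tmin > tmax:
                return None
        return tmin


@dataclass
class Scene:
    colliders: list[Collider]

    def __post_init__(self) -> None:
        canvases = [c for c in self.colliders if c.kind == "canvas"]
        if len(canvases) != 1:
            raise ValueError(f"scene must have exactly one canvas collider, "
                             f"got {len(canvases)}")

    @property
    def canvas(self) -> Collider:
        return next(c for c in self.colliders if c.kind == "canvas")

    def collider(self, object_id: str) -> Collider:
        for c in self.colliders:
            if c.object_id == object_id:
                return c
        raise KeyError(object_id)


@dataclass(frozen=True)
class DistractorActivation:
    object_id: str
    modality: str
    onset: float
    phase_index: int


def distractor_schedule(
    phase_schedule: PhaseSchedule,
    interval: float = DEFAULT_DISTRACTOR_INTERVAL,
    pool_sizes: dict[str, int] | None = None,
    seed: Optional[int] = None,
    n_per_phase: Optional[int] = None,
) -> list[DistractorActivation]:
    """Schedule distractor activations within the DP phases.

    Per distractor phase, ``floor(phase_duration / interval)`` distractors are
    drawn without replacement from the combined visual/auditory/audiovisual
    pool and presented at exact ``interval`` spacing starting at the phase
    onset.  No activations occur during NDP.  Deterministic per seed.
    """
    if interval <= 0:
        raise ValueError("interval must be > 0")
    pools = dict(pool_sizes or DISTRACTOR_POOL_SIZES)
    ids = [
        (f"{mod}_{i:02d}", mod) for mod, n in pools.items() for i in range(n)
    ]
    rng = np.random.default_rng(seed)
    out: list[DistractorActivation] = []
    for pi, entry in enumerate(phase_schedule.entries):
        if entry.phase != Phase.DP:
            continue
        n = int(np.floor(entry.duration / interval)) if n_per_phase is None \
            else n_per_phase
        if n == 0:
            import warnings
            warnings.warn(
                f"distractor interval {interval}s exceeds phase duration "
                f"{entry.duration}s; no events scheduled in phase {pi}"
            )
            continue
        chosen = rng.choice(len(ids), size=n, replace=False)
        for k, ci in enumerate(chosen):
            oid, mod = ids[int(ci)]
            out.append(DistractorActivation(
                object_id=oid, modality=mod,
                onset=entry.start + k * interval, phase_index=pi,
            ))
    return out


def apply_schedule_to_scene(
    scene: Scene,
    activations: Iterable[DistractorActivation],
    linger: float = DEFAULT_DISTRACTOR_LINGER,
) -> None:
    """Attach activation windows (onset + linger) to distractor colliders."""
    for c in scene.colliders:
        if c.kind == "distractor":
            c.active_windows = []
    for act in activations:
        c = scene.collider(act.object_id)
        c.active_windows.append((act.onset, act.onset + linger))


def classify_gaze_sample(
    origin: np.ndarray,
    direction: np.ndarray,
    scene: Scene,
    t: float,
    valid: bool = True,
) -> tuple[str, Optional[str]]:
    """Classify one gaze ray; returns ``(state, hit_object_id)``.

    The nearest intersection among active colliders wins; exact ties are
    broken canvas-first (conservative against false inattention).  Invalid or
    degenerate samples yield the ``invalid`` state.
    """
    d = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(d))
    if not valid or norm < 1e-9 or not np.all(np.isfinite(d)):
        return GazeState.INVALID, None
    d = d / norm
    best: tuple[float, int, Optional[Collider]] = (np.inf, 1, None)
    for c in scene.colliders:
        if not c.active_at(t):
            continue
        hit = c.ray_intersect(origin, d)
        if hit is None:
            continue
        rank = 0 if c.kind == "canvas" else 1  # canvas-first tie-break
        if (hit, rank) < best[:2]:
            best = (hit, rank, c)
    c = best[2]
    if c is None:
        return GazeState.GAZE_WANDERING, None
    if c.kind == "canvas":
        return GazeState.TASK_FOCUS, c.object_id
    if c.kind == "distractor":
        return GazeState.DISTRACTOR_FOCUS, c.object_id
    return GazeState.GAZE_WANDERING, c.object_id


def _ray_intersect_many(c: Collider, o: np.ndarray, d: np.ndarray
                        ) -> np.ndarray:
    """Vectorized ray parameter per sample (NaN where the ray misses)."""
    n = o.shape[0]
    if c.shape == "sphere":
        oc = o - c.center
        b = np.einsum("ij,ij->i", oc, d)
        cc = np.einsum("ij,ij->i", oc, oc) - float(c.extent[0]) ** 2
        disc = b * b - cc
        hit = disc >= 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t1 = -b + sq
        t = np.maximum(-b - sq, 0.0)
        out = np.where(hit & (t1 >= 0), t, np.nan)
        return out
    lo = c.center - c.extent
    hi = c.center + c.extent
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (lo - o) / d
        t1 = (hi - o) / d
        tsmall = np.minimum(t0, t1)
        tbig = np.maximum(t0, t1)
        # parallel axes: inside -> -inf/inf, outside -> miss
        inside = (o >= lo) & (o <= hi)
        par = d == 0.0
        tsmall = np.where(par, np.where(inside, -np.inf, np.inf), tsmall)
        tbig = np.where(par, np.where(inside, np.inf, -np.inf), tbig)
        tmin = np.maximum(tsmall.max(axis=1), 0.0)
        tmax = tbig.min(axis=1)
    return np.where(tmin <= tmax, tmin, np.nan)


def classify_gaze_stream(
    timestamps: np.ndarray,
    origins: np.ndarray,
    directions: np.ndarray,
    scene: Scene,
    valid: Optional[np.ndarray] = None,
) -> tuple[list[str], list[Optional[str]]]:
    """Classify a whole sample stream at once.

    Vectorized over samples but semantically identical to calling
    :func:`classify_gaze_sample` per sample (nearest hit wins, canvas-first
    tie-break, distractor activity windows honoured per sample time).
    """
    timestamps = np.asarray(timestamps, float)
    origins = np.asarray(origins, float)
    d = np.asarray(directions, float)
    n = len(timestamps)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    norms = np.linalg.norm(d, axis=1)
    ok = np.asarray(valid, bool) & (norms > 1e-9) & np.all(np.isfinite(d),
                                                           axis=1)
    dn = np.where(ok[:, None], d / np.where(norms[:, None] == 0, 1.0,
                                            norms[:, None]), 0.0)
    best_t = np.full(n, np.inf)
    best_rank = np.ones(n)  # canvas gets rank 0 for tie-breaks
    best_ci = np.full(n, -1, dtype=int)
    for ci, c in enumerate(scene.colliders):
        t_hit = _ray_intersect_many(c, origins, dn)
        if c.kind == "distractor":
            active = np.zeros(n, dtype=bool)
            for a, b in c.active_windows:
                active |= (timestamps >= a) & (timestamps < b)
            t_hit = np.where(active, t_hit, np.nan)
        rank = 0.0 if c.kind == "canvas" else 1.0
        better = ~np.isnan(t_hit) & (
            (t_hit < best_t) | ((t_hit == best_t) & (rank < best_rank)))
        best_t[better] = t_hit[better]
        best_rank[better] = rank
        best_ci[better] = ci
    states: list[str] = []
    hits: list[Optional[str]] = []
    for i in range(n):
        if not ok[i]:
            states.append(GazeState.INVALID)
            hits.append(None)
        elif best_ci[i] < 0:
            states.append(GazeState.GAZE_WANDERING)
            hits.append(None)
        else:
            c = scene.colliders[best_ci[i]]
            if c.kind == "canvas":
                states.append(GazeState.TASK_FOCUS)
            elif c.kind == "distractor":
                states.append(GazeState.DISTRACTOR_FOCUS)
            else:
                states.append(GazeState.GAZE_WANDERING)
            hits.append(c.object_id)
    return states, hits


@dataclass(frozen=True)
class GazeStateInterval:
    state: str
    start: float
    end: float
    hit_object_id: Optional[str] = None

    @property
    def duration(self) -> float:
        return self.end - self.start


def intervals_from_samples(
    timestamps: np.ndarray,
    states: Sequence[str],
    end_time: Optional[float] = None,
) -> list[GazeStateInterval]:
    """Run-length encode per-sample states into contiguous intervals.

    Each interval ends at the next state-change sample time; the final
    interval ends at ``end_time`` (default: the last timestamp, i.e. the
    covered span equals last - first).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != len(states):
        raise ValueError("timestamps and states must have equal length")
    if len(timestamps) == 0:
        return []
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("samples must be strictly time-ordered")
    if end_time is None:
        end_time = float(timestamps[-1])
    out: list[GazeStateInterval] = []
    run_start = 0
    for i in range(1, len(states)):
        if states[i] != states[run_start]:
            out.append(GazeStateInterval(
                states[run_start], float(timestamps[run_start]),
                float(timestamps[i]),
            ))
            run_start = i
    if end_time > timestamps[run_start]:
        out.append(GazeStateInterval(
            states[run_start], float(timestamps[run_start]), float(end_time)
        ))
    return out


@dataclass
class DwellSummary:
    pct_task_focus: float
    pct_distractor_focus: float
    pct_gaze_wandering: float
    pct_invalid: float
    distractibility_score: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_task_focus": self.pct_task_focus,
            "pct_distractor_focus": self.pct_distractor_focus,
            "pct_gaze_wandering": self.pct_gaze_wandering,
            "pct_invalid": self.pct_invalid,
            "distractibility_score": self.distractibility_score,
        }


def dwell_summary(
    intervals: Sequence[GazeStateInterval],
    block_duration: float,
) -> DwellSummary:
    """Dwell percentages of block duration and the distractibility score.

    Percentages are of total block duration including invalid (blink) time;
    uncovered time (before the first / after the last sample) counts as
    invalid so the four percentages always sum to 100.
    """
    if block_duration <= 0:
        raise ValueError("block_duration must be > 0")
    totals = {s: 0.0 for s in GazeState.ALL}
    for iv in intervals:
        if iv.duration < 0:
            raise ValueError(f"negative interval {iv}")
        totals[iv.state] += iv.duration
    covered = sum(totals.values())
    if covered - block_duration > 1e-6:
        raise ValueError("intervals exceed the block duration")
    totals[GazeState.INVALID] += block_duration - covered
    pct = {s: 100.0 * v / block_duration for s, v in totals.items()}
    if pct[GazeState.TASK_FOCUS] == 0:
        raise ZeroDivisionError(
            "distractibility score undefined: task-focus time is zero"
        )
    score = (
        pct[GazeState.DISTRACTOR_FOCUS] + pct[GazeState.GAZE_WANDERING]
    ) / pct[GazeState.TASK_FOCUS]
    return DwellSummary(
        pct_task_focus=pct[GazeState.TASK_FOCUS],
        pct_distractor_focus=pct[GazeState.DISTRACTOR_FOCUS],
        pct_gaze_wandering=pct[GazeState.GAZE_WANDERING],
        pct_invalid=pct[GazeState.INVALID],
        distractibility_score=score,
    )


def default_scene(pool_sizes: dict[str, int] | None = None) -> Scene:
    """A seminar-room-like proxy scene.

    The viewer sits at the origin looking along +z.  The canvas is a 2 m x
    1.5 m box 3 m ahead at eye height.  Distractor colliders (one per pool
    item) are placed on a ring around the viewer, off-canvas, as generous
    boxes; auditory distractors get slightly larger volumes standing in for
    sound-source regions.
    """
    pools = dict(pool_sizes or DISTRACTOR_POOL_SIZES)
    colliders = [Collider(
        object_id="canvas", kind="canvas", shape="box",
        center=np.array([0.0, 1.2, 3.0]),
        extent=np.array([1.0, 0.75, 0.05]),
    )]
    n_total = sum(pools.values())
    i = 0
    for mod, n in pools.items():
        for k in range(n):
            # ring positions avoiding the canvas cone (|azimuth| > 25 deg)
            az = np.deg2rad(30.0 + 300.0 * (i / max(n_total, 1)))
            r = 2.5
            center = np.array([r * np.sin(az), 1.0 + 0.5 * ((i % 3) - 1),
                               r * np.cos(az)])
            half = 0.45 if mod == "auditory" else 0.3
            colliders.append(Collider(
                object_id=f"{mod}_{k:02d}", kind="distractor", shape="box",
                center=center, extent=np.array([half, half, half]),
            ))
            i += 1
    return Scene(colliders)
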