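"""Canonical session data model, multimodal stream I/O and phase scheduling.

A recording session consists of three 18-minute task blocks (one per feedback
condition), each carrying several independently clocked time series: binocular
gaze (~50 Hz), head position (~90 Hz), EEG (500 Hz), the letter-stream task
schedule, keypress responses and feedback events.  All streams of one block
share a single session clock in seconds with t = 0 at block start.  Time
windows are half-open ``[start, end)`` throughout the package, so slicing a
stream by the phases of a schedule partitions its samples exactly.

Streams with different nominal rates are never resampled implicitly; alignment
is by timestamp filtering only.  Units are fixed package-wide: seconds, meters,
microvolts, and degrees for oculomotor outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Condition",
    "PhaseEntry",
    "PhaseSchedule",
    "TimeSeriesStream",
    "BlockRecord",
    "SessionRecord",
    "build_phase_schedule",
    "slice_stream",
    "read_session",
    "write_session",
    "EEG_CHANNELS",
]

#: The 24 scalp electrodes of the 10-20 montage used for the EEG stream.
EEG_CHANNELS = (
    "Fp1", "Fp2", "AFz", "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "CPz", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "O2", "M1", "M2",
)

#: Standard block layout: six alternating 3-minute phases, 18 minutes total.
STANDARD_PHASE_SECONDS = 180.0
STANDARD_N_PHASES = 6
STANDARD_BLOCK_SECONDS = STANDARD_PHASE_SECONDS * STANDARD_N_PHASES


class Phase(str, Enum):
    """Distractor phase (DP) vs. non-distractor phase (NDP)."""

    DP = "DP"
    NDP = "NDP"

    @property
    def other(self) -> "Phase":
        return Phase.NDP if self is Phase.DP else Phase.DP


class Condition(str, Enum):
    """Feedback condition of a task block."""

    REAL = "real"
    SHAM = "sham"
    NONE = "none"


CONDITIONS = (Condition.REAL, Condition.SHAM, Condition.NONE)


@dataclass(frozen=True)
class PhaseEntry:
    phase: Phase
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous, strictly alternating sequence of DP/NDP phases."""

    entries: tuple[PhaseEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("PhaseSchedule requires at least one entry")
        prev = None
        for e in self.entries:
            if e.end <= e.start:
                raise ValueError(f"phase entry has non-positive duration: {e}")
            if prev is not None:
                if e.start != prev.end:
                    raise ValueError(
                        f"schedule not contiguous: {prev.end} -> {e.start}"
                    )
                if e.phase == prev.phase:
                    raise ValueError("phase types must strictly alternate")
            prev = e

    @property
    def start(self) -> float:
        return self.entries[0].start

    @property
    def end(self) -> float:
        return self.entries[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    def phase_at(self, t: float) -> Optional[Phase]:
        """Phase containing time ``t`` (half-open windows), or None."""
        for e in self.entries:
            if e.start <= t < e.end:
                return e.phase
        return None

    def windows(self, phase: Phase) -> list[tuple[float, float]]:
        """All ``[start, end)`` windows belonging to ``phase``."""
        return [(e.start, e.end) for e in self.entries if e.phase == phase]


def build_phase_schedule(
    start_phase: Phase | str,
    n_phases: int,
    phase_seconds: float,
    start: float = 0.0,
) -> PhaseSchedule:
    """Build a contiguous alternating DP/NDP schedule.

    Parameters
    ----------
    start_phase
        Phase type of the first entry.
    n_phases
        Number of phases (>= 1).
    phase_seconds
        Duration of every phase in seconds (> 0).  The standard block uses
        six phases of 180 s (18 minutes total).
    """
    if n_phases < 1:
        raise ValueError(f"n_phases must be >= 1, got {n_phases}")
    if phase_seconds <= 0:
        raise ValueError(f"phase_seconds must be > 0, got {phase_seconds}")
    p = Phase(start_phase)
    entries = []
    # boundaries computed from one shared expression so consecutive entries
    # are bitwise contiguous even when i * phase_seconds does not round trip
    bounds = [start + i * phase_seconds for i in range(n_phases + 1)]
    for i in range(n_phases):
        entries.append(PhaseEntry(p, bounds[i], bounds[i + 1]))
        p = p.other
    return PhaseSchedule(tuple(entries))


@dataclass
class TimeSeriesStream:
    """A named, uniformly sampled (nominally) multichannel time series.

    Attributes
    ----------
    name
        Stream identifier (``"gaze"``, ``"head"``, ``"eeg"``...).
    nominal_rate
        Nominal sampling rate in Hz (> 0); the timestamps are authoritative.
    channels
        Ordered channel names, one per value column.
    timestamps
        Strictly increasing sample times in seconds.
    values
        ``(n_samples, n_channels)`` float array.
    validity
        Optional per-sample boolean flags (e.g. eye-tracker validity).
    """

    name: str
    nominal_rate: float
    channels: tuple[str, ...]
    timestamps: np.ndarray
    values: np.ndarray
    validity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.channels = tuple(self.channels)
        if self.nominal_rate <= 0:
            raise ValueError(f"nominal_rate must be > 0, got {self.nominal_rate}")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"stream {self.name!r}: values shape {self.values.shape} does "
                f"not match {len(self.channels)} channels"
            )
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError(
                f"stream {self.name!r}: {self.values.shape[0]} value rows for "
                f"{self.timestamps.shape[0]} timestamps"
            )
        if self.timestamps.size > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValueError(
                    f"stream {self.name!r}: timestamps not strictly increasing "
                    f"at row {row}"
                )
        if self.validity is not None:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape[0] != self.timestamps.shape[0]:
                raise ValueError(f"stream {self.name!r}: validity length mismatch")

    def __len__(self) -> int:
        return int(self.timestamps.shape[0])

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]


def slice_stream(
    stream: TimeSeriesStream, start: float, end: float
) -> TimeSeriesStream:
    """Samples with ``start <= t < end``; an empty result is a valid stream."""
    if not start < end:
        raise ValueError(f"require start < end, got [{start}, {end})")
    mask = (stream.timestamps >= start) & (stream.timestamps < end)
    return TimeSeriesStream(
        name=stream.name,
        nominal_rate=stream.nominal_rate,
        channels=stream.channels,
        timestamps=stream.timestamps[mask],
        values=stream.values[mask],
        validity=None if stream.validity is None else stream.validity[mask],
    )


@dataclass
class BlockRecord:
    """One task block: a feedback condition with all its recorded streams."""

    condition: Condition
    phase_schedule: PhaseSchedule
    gaze: TimeSeriesStream
    head: TimeSeriesStream
    cpt_block: "object"  # gart.cpt.CPTBlock
    responses: np.ndarray
    feedback_events: list = field(default_factory=list)
    eeg: Optional[TimeSeriesStream] = None
    experience_sampling: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.responses = np.asarray(self.responses, dtype=float)
        for k, v in self.experience_sampling.items():
            if not -3 <= int(v) <= 3:
                raise ValueError(
                    f"experience sampling {k!r}={v} outside Likert range [-3, 3]"
                )


@dataclass
class SessionRecord:
    """A full participant session: three counterbalanced blocks."""

    participant_id: str
    group: str  # "ADHD" | "HC"
    condition_order: tuple[Condition, ...]
    blocks: list[BlockRecord]
    recognition_responses: Optional[np.ndarray] = None
    recognition_truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.group not in ("ADHD", "HC"):
            raise ValueError(f"group must be 'ADHD' or 'HC', got {self.group!r}")
        self.condition_order = tuple(Condition(c) for c in self.condition_order)
        if sorted(c.value for c in self.condition_order) != sorted(
            c.value for c in CONDITIONS
        ):
            raise ValueError(
                f"condition_order must be a permutation of the three "
                f"conditions, got {self.condition_order}"
            )
        if len(self.blocks) != 3:
            raise ValueError(f"expected exactly 3 blocks, got {len(self.blocks)}")
        for blk, cond in zip(self.blocks, self.condition_order):
            if blk.condition != cond:
                raise ValueError(
                    f"block condition {blk.condition} does not match "
                    f"condition_order entry {cond}"
                )

    def block(self, condition: Condition | str) -> BlockRecord:
        condition = Condition(condition)
        for blk in self.blocks:
            if blk.condition == condition:
                return blk
        raise KeyError(condition)


# ---------------------------------------------------------------------------
# I/O: per-block CSV files plus a session-level JSON manifest.
# ---------------------------------------------------------------------------

GAZE_COLUMNS = (
    "t", "lx", "ly", "lz", "ldx", "ldy", "ldz", "validity_l",
    "rx", "ry", "rz", "rdx", "rdy", "rdz", "validity_r",
)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _check_monotonic(t: np.ndarray, path: Path) -> None:
    if t.size > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            # +2: one for the diff offset, one for the CSV header line
            raise ValueError(
                f"{path}: non-monotonic timestamp at data row {bad[0] + 2}"
            )


def _read_stream_csv(
    path: Path, name: str, rate: float, channels: Sequence[str]
) -> TimeSeriesStream:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t", *channels], path)
    t = df["t"].to_numpy(float)
    _check_monotonic(t, path)
    return TimeSeriesStream(
        name=name,
        nominal_rate=rate,
        channels=tuple(channels),
        timestamps=t,
        values=df[list(channels)].to_numpy(float),
    )


def _read_gaze_csv(path: Path, rate: float) -> TimeSeriesStream:
    df = pd.read_csv(path, float_precision="round_trip")
    core = [c for c in GAZE_COLUMNS if not c.startswith("validity")]
    _require_columns(df, core, path)
    for vcol in ("validity_l", "validity_r"):
        if vcol not in df.columns:
            warnings.warn(
                f"{path}: column {vcol!r} absent; assuming all samples valid"
            )
            df[vcol] = 1
    t = df["t"].to_numpy(float)
    _check_monotonic(t, path)
    channels = tuple(c for c in GAZE_COLUMNS if c != "t")
    values = df[list(channels)].to_numpy(float)
    valid = (df["validity_l"].to_numpy(float) > 0) | (
        df["validity_r"].to_numpy(float) > 0
    )
    return TimeSeriesStream(
        name="gaze", nominal_rate=rate, channels=channels,
        timestamps=t, values=values, validity=valid,
    )


def _block_dir(root: Path, index: int, condition: Condition) -> Path:
    return root / f"block{index}_{condition.value}"


def write_session(session: SessionRecord, root: str | Path) -> Path:
    """Write a session as per-block CSV files plus ``session.json``."""
    from .cpt import write_cpt_csv
    from .feedback import write_feedback_csv

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "participant_id": session.participant_id,
        "group": session.group,
        "condition_order": [c.value for c in session.condition_order],
        "blocks": [],
    }
    if session.recognition_responses is not None:
        manifest["recognition"] = {
            "responses": np.asarray(session.recognition_responses, bool).tolist(),
            "truth": np.asarray(session.recognition_truth, bool).tolist(),
        }
    for i, blk in enumerate(session.blocks):
        bdir = _block_dir(root, i, blk.condition)
        bdir.mkdir(parents=True, exist_ok=True)
        g = blk.gaze
        gdf = pd.DataFrame(g.values, columns=list(g.channels))
        gdf.insert(0, "t", g.timestamps)
        gdf.to_csv(bdir / "gaze.csv", index=False, float_format="%.17g")
        h = blk.head
        hdf = pd.DataFrame(h.values, columns=list(h.channels))
        hdf.insert(0, "t", h.timestamps)
        hdf.to_csv(bdir / "head.csv", index=False, float_format="%.17g")
        if blk.eeg is not None:
            e = blk.eeg
            edf = pd.DataFrame(e.values, columns=list(e.channels))
            edf.insert(0, "t", e.timestamps)
            edf.to_csv(bdir / "eeg.csv", index=False, float_format="%.17g")
        write_cpt_csv(blk.cpt_block, bdir / "cpt.csv")
        pd.DataFrame({"t": blk.responses}).to_csv(
            bdir / "responses.csv", index=False, float_format="%.17g")
        write_feedback_csv(blk.feedback_events, blk.condition.value,
                           bdir / "feedback.csv")
        manifest["blocks"].append({
            "index": i,
            "condition": blk.condition.value,
            "phase_schedule": [
                [e.phase.value, e.start, e.end] for e in blk.phase_schedule.entries
            ],
            "experience_sampling": {k: int(v) for k, v in
                                    blk.experience_sampling.items()},
        })
    (root / "session.json").write_text(json.dumps(manifest, indent=1))
    return root


def read_session(root: str | Path) -> SessionRecord:
    """Read a session written by :func:`write_session`."""
    from .cpt import read_cpt_csv
    from .feedback import read_feedback_csv

    root = Path(root)
    manifest = json.loads((root / "session.json").read_text())
    blocks = []
    for meta in manifest["blocks"]:
        cond = Condition(meta["condition"])
        bdir = _block_dir(root, meta["index"], cond)
        schedule = PhaseSchedule(tuple(
            PhaseEntry(Phase(p), float(a), float(b))
            for p, a, b in meta["phase_schedule"]
        ))
        gaze = _read_gaze_csv(bdir / "gaze.csv", rate=50.0)
        head = _read_stream_csv(bdir / "head.csv", "head", 90.0, ("x", "y", "z"))
        eeg = None
        if (bdir / "eeg.csv").exists():
            eeg = _read_stream_csv(bdir / "eeg.csv", "eeg", 500.0, EEG_CHANNELS)
        cpt_block = read_cpt_csv(bdir / "cpt.csv")
        responses = pd.read_csv(
            bdir / "responses.csv",
            float_precision="round_trip")["t"].to_numpy(float)
        feedback_events = read_feedback_csv(bdir / "feedback.csv")
        blocks.append(BlockRecord(
            condition=cond,
            phase_schedule=schedule,
            gaze=gaze,
            head=head,
            eeg=eeg,
            cpt_block=cpt_block,
            responses=responses,
            feedback_events=feedback_events,
            experience_sampling={k: int(v) for k, v in
                                 meta["experience_sampling"].items()},
        ))
    rec = manifest.get("recognition")
    return SessionRecord(
        participant_id=manifest["participant_id"],
        group=manifest["group"],
        condition_order=tuple(Condition(c) for c in manifest["condition_order"]),
        blocks=blocks,
        recognition_responses=None if rec is None else np.asarray(
            rec["responses"], bool),
        recognition_truth=None if rec is None else np.asarray(rec["truth"], bool),
    )
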