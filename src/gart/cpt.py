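"""Continuous performance task: stimulus generation and response scoring.

The task presents single uppercase letters centrally (100 ms stimulus,
1100 ms inter-stimulus interval, 900 trials per 18-minute block) and requires
a keypress whenever a 'K' follows an 'A'.  Trial classes are defined on
letter *transitions*: the first trial is an unclassifiable "opener", and each
of the remaining ``n - 1`` trials is classified by its (previous, current)
letter pair:

* ``target``        — (A, K)
* ``pseudo_target`` — any other pair containing at least one of {A, K}
* ``nontarget``     — neither letter is A or K

A block realizes 30% targets among classifiable trials, and 50% of the
non-target remainder are pseudo-targets.  Counts are rounded half-up; the
remainder is filled with plain non-targets.

Scoring maps each keypress to the most recent stimulus onset within the
response window (default: one full stimulus-onset asynchrony, 1.2 s).  A
response to a target is a hit with a reaction time in ms; a response to any
other trial is a commission error; a target without a response in its window
is an omission error.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session import Phase, PhaseSchedule

__all__ = [
    "TrialClass",
    "LetterTrial",
    "CPTBlock",
    "CPTPerformance",
    "generate_cpt_block",
    "classify_letter_stream",
    "score_cpt",
    "split_performance_by_phase",
    "read_cpt_csv",
    "write_cpt_csv",
]

TARGET_LETTERS = frozenset("AK")
#: Letters used for "neither" slots: the alphabet minus the two target letters.
NEUTRAL_LETTERS = tuple(c for c in string.ascii_uppercase if c not in "AK")

DEFAULT_STIMULUS_DURATION = 0.100
DEFAULT_ISI = 1.100
DEFAULT_N_TRIALS = 900
DEFAULT_P_TARGET = 0.30
DEFAULT_P_PSEUDO = 0.50  # share of pseudo-targets within non-target trials
#: Default response window: one stimulus-onset asynchrony.
DEFAULT_RESPONSE_WINDOW = DEFAULT_STIMULUS_DURATION + DEFAULT_ISI


class TrialClass:
    OPENER = "opener"
    TARGET = "target"
    PSEUDO = "pseudo_target"
    NONTARGET = "nontarget"


@dataclass(frozen=True)
class LetterTrial:
    index: int
    letter: str
    onset: float
    trial_class: str


@dataclass
class CPTBlock:
    """An ordered letter stream with onsets and per-trial classes."""

    trials: list[LetterTrial]
    stimulus_duration: float = DEFAULT_STIMULUS_DURATION
    isi: float = DEFAULT_ISI
    seed: Optional[int] = None

    @property
    def letters(self) -> str:
        return "".join(t.letter for t in self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony."""
        return self.stimulus_duration + self.isi

    @property
    def duration(self) -> float:
        return len(self.trials) * self.soa

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.trial_class] = counts.get(t.trial_class, 0) + 1
        return counts


def classify_letter_stream(letters: str) -> list[str]:
    """Per-trial classes from the raw letter stream (independent of onsets)."""
    classes = [TrialClass.OPENER]
    for prev, cur in zip(letters, letters[1:]):
        if prev == "A" and cur == "K":
            classes.append(TrialClass.TARGET)
        elif prev in TARGET_LETTERS or cur in TARGET_LETTERS:
            classes.append(TrialClass.PSEUDO)
        else:
            classes.append(TrialClass.NONTARGET)
    return classes


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _compose_counts(n_classifiable: int, p_target: float, p_pseudo: float
                    ) -> tuple[int, int, int]:
    n_target = _round_half_up(p_target * n_classifiable)
    n_pseudo = _round_half_up(p_pseudo * (1.0 - p_target) * n_classifiable)
    n_non = n_classifiable - n_target - n_pseudo
    if n_non < 0:
        raise ValueError(
            f"infeasible composition: target+pseudo counts "
            f"{n_target}+{n_pseudo} exceed {n_classifiable} classifiable trials"
        )
    return n_target, n_pseudo, n_non


def generate_cpt_block(
    seed: Optional[int] = None,
    n_trials: int = DEFAULT_N_TRIALS,
    p_target: float = DEFAULT_P_TARGET,
    p_pseudo: float = DEFAULT_P_PSEUDO,
    stimulus_duration: float = DEFAULT_STIMULUS_DURATION,
    isi: float = DEFAULT_ISI,
) -> CPTBlock:
    """Generate a letter stream realizing the requested class composition.

    The stream is built from letter runs: runs of neutral letters produce
    non-target transitions, and runs of target letters (A/K alternations plus
    'A' padding) produce the scheduled targets and pseudo-targets.  Every
    target transition (A, K) is necessarily flanked by pseudo-target
    transitions, which constrains feasibility: the construction requires at
    least ``n_target + 1`` pseudo-targets when targets are present.

    Deterministic for a given ``seed``; no accidental target can occur because
    (A, K) adjacencies are only ever emitted for scheduled targets.
    """
    if n_trials < 2:
        raise ValueError(f"n_trials must be >= 2, got {n_trials}")
    if not (0 <= p_target <= 1 and 0 <= p_pseudo <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cls = n_trials - 1
    n_target, n_pseudo, n_non = _compose_counts(n_cls, p_target, p_pseudo)

    if n_target > 0 and n_pseudo < n_target + 1:
        raise ValueError(
            f"infeasible composition: {n_target} targets require at least "
            f"{n_target + 1} pseudo-targets (got {n_pseudo}); every target "
            f"needs flanking transitions that contain a target letter"
        )

    # Special runs: each contributes (entry + internal + exit) transitions.
    # A run of m target-letters with t targets yields t target transitions
    # and (m + 1 - t) pseudo transitions; it needs m >= 2 t (built as
    # "AK" * t padded with 'A').  With s runs: sum(m_i) = n_target +
    # n_pseudo - s, so feasibility needs n_pseudo >= n_target + s.
    if n_target == 0 and n_pseudo == 1:
        # a lone pseudo transition is only realizable at the stream end
        letters = [str(c) for c in rng.choice(NEUTRAL_LETTERS, n_trials - 1)]
        letters.append("A")
        return _finalize_block(letters, n_target, n_pseudo,
                               stimulus_duration, isi, seed)
    if n_target == 0 and n_pseudo == 0:
        s = 0
    elif n_target == 0:
        # each run consumes >= 1 letter on top of its entry transition
        s = int(rng.integers(1, max(1, n_pseudo // 2) + 1))
    else:
        # Worst-case padding need is 2*t per target-bearing run plus 1 per
        # empty run, so capping s at (n_pseudo - n_target + 1) // 2 keeps any
        # random split of targets over runs realizable.
        s_max = max(1, (n_pseudo - n_target + 1) // 2)
        s = int(rng.integers(1, s_max + 1))

    letters: list[str] = []
    if s == 0:
        # Plain neutral stream: n_trials letters, all transitions non-target.
        letters = [str(rng.choice(NEUTRAL_LETTERS)) for _ in range(n_trials)]
    else:
        # Distribute targets over runs, then pad runs to consume the pseudos.
        t_parts = rng.multinomial(n_target, np.ones(s) / s)
        m_total = n_target + n_pseudo - s
        m_min = np.maximum(1, 2 * t_parts)
        slack = m_total - int(m_min.sum())
        assert slack >= 0, "internal feasibility check failed"
        extra = rng.multinomial(slack, np.ones(s) / s)
        m_parts = m_min + extra
        # Neutral letters: s+1 runs of length >= 1, n_non internal adjacencies.
        o_total = n_non + s + 1
        o_parts = np.ones(s + 1, dtype=int)
        o_parts += rng.multinomial(o_total - (s + 1), np.ones(s + 1) / (s + 1))

        def neutral_run(k: int) -> list[str]:
            return [str(c) for c in rng.choice(NEUTRAL_LETTERS, size=k)]

        letters.extend(neutral_run(int(o_parts[0])))
        for i in range(s):
            t_i, m_i = int(t_parts[i]), int(m_parts[i])
            run = list("AK" * t_i) + ["A"] * (m_i - 2 * t_i)
            letters.extend(run)
            letters.extend(neutral_run(int(o_parts[i + 1])))

    return _finalize_block(letters, n_target, n_pseudo,
                           stimulus_duration, isi, seed)


def _finalize_block(letters: list[str], n_target: int, n_pseudo: int,
                    stimulus_duration: float, isi: float,
                    seed: Optional[int]) -> CPTBlock:
    n_trials = len(letters)
    classes = classify_letter_stream("".join(letters))
    realized = {c: classes.count(c) for c in set(classes)}
    assert realized.get(TrialClass.TARGET, 0) == n_target
    assert realized.get(TrialClass.PSEUDO, 0) == n_pseudo

    soa = stimulus_duration + isi
    trials = [
        LetterTrial(i, letters[i], i * soa, classes[i]) for i in range(n_trials)
    ]
    return CPTBlock(trials=trials, stimulus_duration=stimulus_duration,
                    isi=isi, seed=seed)


@dataclass
class CPTPerformance:
    omission_errors: int
    commission_errors: int
    reaction_times: np.ndarray  # ms, hits only
    n_targets: int
    n_nontargets: int  # all non-target classifiable trials (incl. pseudo)
    n_ignored_responses: int = 0

    @property
    def hits(self) -> int:
        return self.n_targets - self.omission_errors

    @property
    def mean_rt(self) -> float:
        return float(np.mean(self.reaction_times)) if len(
            self.reaction_times) else float("nan")


def score_cpt(
    block: CPTBlock,
    responses: Sequence[float] | np.ndarray,
    response_window: float = DEFAULT_RESPONSE_WINDOW,
) -> CPTPerformance:
    """Score keypress timestamps against the letter stream.

    Each response is assigned to the most recent stimulus onset within
    ``response_window`` seconds before it; only the first response within one
    trial's window counts.  Responses preceding the first onset (or falling
    in no window) are ignored and counted.
    """
    if response_window <= 0:
        raise ValueError("response_window must be > 0")
    responses = np.asarray(responses, dtype=float)
    if responses.size > 1 and np.any(np.diff(responses) < 0):
        raise ValueError("responses must be sorted ascending")
    onsets = block.onsets
    n = len(block.trials)
    responded = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    n_ignored = 0
    idx = np.searchsorted(onsets, responses, side="right") - 1
    for r, i in zip(responses, idx):
        if i < 0 or r - onsets[i] >= response_window:
            n_ignored += 1
            continue
        if not responded[i]:
            responded[i] = True
            rt[i] = (r - onsets[i]) * 1000.0
    omissions = commissions = 0
    n_targets = n_nontargets = 0
    hit_rts = []
    for t in block.trials:
        if t.trial_class == TrialClass.TARGET:
            n_targets += 1
            if responded[t.index]:
                hit_rts.append(rt[t.index])
            else:
                omissions += 1
        else:
            n_nontargets += 1
            if responded[t.index]:
                commissions += 1
    if n_ignored:
        warnings.warn(f"{n_ignored} responses outside any response window")
    return CPTPerformance(
        omission_errors=omissions,
        commission_errors=commissions,
        reaction_times=np.asarray(hit_rts),
        n_targets=n_targets,
        n_nontargets=n_nontargets,
        n_ignored_responses=n_ignored,
    )


def split_performance_by_phase(
    block: CPTBlock,
    responses: Sequence[float] | np.ndarray,
    schedule: PhaseSchedule,
    response_window: float = DEFAULT_RESPONSE_WINDOW,
) -> dict[Phase, CPTPerformance]:
    """Per-phase-type scores; a trial belongs to the phase containing its onset.

    Half-open windows assign a trial whose onset falls exactly on a boundary
    to the later phase.  Per-phase counts sum to the whole-block totals.
    """
    if schedule.start > 0 or schedule.end < block.duration - block.soa:
        raise ValueError(
            f"schedule [{schedule.start}, {schedule.end}) does not cover the "
            f"block's trial onsets"
        )
    full = _assignments(block, np.asarray(responses, float), response_window)
    out: dict[Phase, CPTPerformance] = {}
    for phase in (Phase.DP, Phase.NDP):
        omissions = commissions = n_targets = n_nontargets = 0
        hit_rts = []
        for t in block.trials:
            p = schedule.phase_at(t.onset)
            if p is None:
                raise ValueError(f"trial onset {t.onset} falls in a schedule gap")
            if p != phase:
                continue
            responded, rt_ms = full[t.index]
            if t.trial_class == TrialClass.TARGET:
                n_targets += 1
                if responded:
                    hit_rts.append(rt_ms)
                else:
                    omissions += 1
            else:
                n_nontargets += 1
                if responded:
                    commissions += 1
        out[phase] = CPTPerformance(
            omission_errors=omissions,
            commission_errors=commissions,
            reaction_times=np.asarray(hit_rts),
            n_targets=n_targets,
            n_nontargets=n_nontargets,
        )
    return out


def _assignments(block: CPTBlock, responses: np.ndarray, window: float
                 ) -> dict[int, tuple[bool, float]]:
    onsets = block.onsets
    out = {t.index: (False, float("nan")) for t in block.trials}
    idx = np.searchsorted(onsets, responses, side="right") - 1
    for r, i in zip(responses, idx):
        if i < 0 or r - onsets[i] >= window:
            continue
        if not out[i][0]:
            out[i] = (True, (r - onsets[i]) * 1000.0)
    return out


def write_cpt_csv(block: CPTBlock, path: str | Path) -> None:
    df = pd.DataFrame({
        "trial": [t.index for t in block.trials],
        "letter": [t.letter for t in block.trials],
        "onset": [t.onset for t in block.trials],
        "class": [t.trial_class for t in block.trials],
    })
    df.attrs["stimulus_duration"] = block.stimulus_duration
    with open(path, "w") as fh:
        fh.write(f"# stimulus_duration={block.stimulus_duration} isi={block.isi}\n")
        df.to_csv(fh, index=False)


def read_cpt_csv(path: str | Path) -> CPTBlock:
    with open(path) as fh:
        header = fh.readline()
        params = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh, float_precision="round_trip")
    trials = [
        LetterTrial(int(r.trial), str(r.letter), float(r.onset), str(r["class"]))
        for _, r in df.iterrows()
    ]
    return CPTBlock(
        trials=trials,
        stimulus_duration=float(params["stimulus_duration"]),
        isi=float(params["isi"]),
    )
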