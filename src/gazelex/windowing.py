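"""Onset alignment, window summaries, 20 ms binning, and exclusion rules.

Timing convention: after alignment, 0 is target-word onset.  The pre-naming
window [0, 367) ms covers the saccade-programming latency during which gaze
cannot yet reflect the word heard; the analysis window [367, 3500) ms is where
word-driven looking is measured.  All windows are half-open.

Exclusion rules, applied per trial:

* ``NO_PRENAMING_LOOK`` — the infant never looked to either display in [0, 367)
* ``CRYING``            — coders flagged active crying
* ``MIN_LOOKING``       — on-display time in the analysis window is strictly
  below one third of it (3133/3 ms; compared exactly, as 3*looking < 3133)
* ``ADULT_ERROR``       — caregiver or experimenter error flag

A subject is retained only if they contribute usable data on at least half of
the experiment's designed trial count (16 of 32 nouns trials, 4 of 8
honorifics trials).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GazelexError
from .types import (
    DESIGN_TRIALS,
    AlignedLook,
    AlignedTrial,
    BinSeries,
    Direction,
    ExclusionReason,
    ExclusionResult,
    LookRecord,
    Role,
    Session,
    Trial,
    TrialSpec,
    Window,
    WindowSummary,
)

PRENAMING = Window("PRENAMING", 0.0, 367.0)
ANALYSIS = Window("ANALYSIS", 367.0, 3500.0)
PLOT = Window("PLOT", -1000.0, 3500.0)

#: Minimum on-display time in the analysis window, as an exact rational:
#: a trial is excluded iff 3 * looking_ms < MIN_LOOKING_NUMERATOR_MS.
MIN_LOOKING_NUMERATOR_MS = 3133

DEFAULT_BIN_MS = 20.0


def role_for(direction: Direction, target_side: Direction) -> Role:
    """Map a screen direction to TARGET/DISTRACTOR/AWAY given the target side."""
    if direction is Direction.AWAY:
        return Role.AWAY
    return Role.TARGET if direction is target_side else Role.DISTRACTOR


def align_trial(spec: TrialSpec, looks: Sequence[LookRecord]) -> AlignedTrial:
    """Shift look times by -target_onset_ms and relabel sides as roles.

    Looks spanning the onset are kept whole (clipping is the window
    summarizer's job); pre-onset times come out negative.
    """
    aligned = tuple(
        AlignedLook(
            role=role_for(lk.direction, spec.target_side),
            onset_ms=lk.onset_ms - spec.target_onset_ms,
            offset_ms=lk.offset_ms - spec.target_onset_ms,
        )
        for lk in looks
    )
    return AlignedTrial(spec=spec, looks=aligned)


def align_session(session: Session) -> list[AlignedTrial]:
    return [align_trial(t.spec, t.looks) for t in session.trials]


def summarize_window(trial: AlignedTrial, window: Window) -> WindowSummary:
    """Clip looks to the window and total the time in each role.

    Uncoded time (gaps between looks) counts as AWAY, so the three role
    durations always sum exactly to the window duration.
    """
    target = 0.0
    distractor = 0.0
    coded_away = 0.0
    for lk in trial.looks:
        lo = max(lk.onset_ms, window.start_ms)
        hi = min(lk.offset_ms, window.end_ms)
        if hi <= lo:
            continue
        if lk.role is Role.TARGET:
            target += hi - lo
        elif lk.role is Role.DISTRACTOR:
            distractor += hi - lo
        else:
            coded_away += hi - lo
    away = window.duration_ms - target - distractor
    return WindowSummary(
        trial_id=trial.spec.trial_id,
        window=window,
        target_ms=target,
        distractor_ms=distractor,
        away_ms=away,
    )


def _occupancy(
    trial: AlignedTrial, starts: np.ndarray, bin_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin ms of TARGET and DISTRACTOR occupancy (vectorized over bins)."""
    n = len(starts)
    tgt = np.zeros(n)
    dst = np.zeros(n)
    ends = starts + bin_ms
    for lk in trial.looks:
        if lk.role is Role.AWAY:
            continue
        ov = np.minimum(ends, lk.offset_ms) - np.maximum(starts, lk.onset_ms)
        np.maximum(ov, 0.0, out=ov)
        if lk.role is Role.TARGET:
            tgt += ov
        else:
            dst += ov
    return tgt, dst


def _state_at(trial: AlignedTrial, t: np.ndarray) -> np.ndarray:
    """Role code (0=T, 1=D, 2=A) of the look covering each instant t (half-open)."""
    out = np.full(len(t), 2, dtype=np.int8)
    for lk in trial.looks:
        if lk.role is Role.AWAY:
            continue
        mask = (t >= lk.onset_ms) & (t < lk.offset_ms)
        out[mask] = 0 if lk.role is Role.TARGET else 1
    return out


_ROLE_BY_CODE = (Role.TARGET, Role.DISTRACTOR, Role.AWAY)


def bin_window(
    trial: AlignedTrial, window: Window, bin_ms: float = DEFAULT_BIN_MS
) -> BinSeries:
    """Reduce a trial to a single gaze state per fixed-width bin.

    Bin k covers [start + k*bin_ms, start + (k+1)*bin_ms).  The bin's state is
    the role occupying the majority of it; ties break toward the role active
    at the bin's first instant (then TARGET > DISTRACTOR > AWAY).  A trailing
    partial bin is dropped, so the analysis window yields floor(3133/20) = 156
    bins at the default width.
    """
    if bin_ms >= window.duration_ms:
        raise GazelexError(
            f"bin_ms={bin_ms} does not fit inside window "
            f"{window.name} of {window.duration_ms} ms"
        )
    n_bins = int(np.floor(window.duration_ms / bin_ms))
    starts = window.start_ms + bin_ms * np.arange(n_bins)
    tgt, dst = _occupancy(trial, starts, bin_ms)
    away = bin_ms - tgt - dst
    occ = np.stack([tgt, dst, away])  # (3, n_bins)
    start_state = _state_at(trial, starts)

    best = occ.max(axis=0)
    states = []
    for k in range(n_bins):
        tied = [c for c in range(3) if occ[c, k] >= best[k] - 1e-9]
        if len(tied) == 1:
            code = tied[0]
        elif start_state[k] in tied:
            code = int(start_state[k])
        else:
            code = min(tied)  # TARGET > DISTRACTOR > AWAY priority
        states.append(_ROLE_BY_CODE[code])
    return BinSeries(
        trial_id=trial.spec.trial_id,
        window=window,
        bin_ms=bin_ms,
        states=tuple(states),
    )


def classify_trial(spec: TrialSpec, trial: AlignedTrial) -> ExclusionResult:
    """Apply all trial-level exclusion rules; every applicable reason is recorded."""
    reasons = set()
    pre = summarize_window(trial, PRENAMING)
    if pre.looking_ms == 0:
        reasons.add(ExclusionReason.NO_PRENAMING_LOOK)
    if spec.crying_flag:
        reasons.add(ExclusionReason.CRYING)
    ana = summarize_window(trial, ANALYSIS)
    if 3.0 * ana.looking_ms < MIN_LOOKING_NUMERATOR_MS:
        reasons.add(ExclusionReason.MIN_LOOKING)
    if spec.error_flag:
        reasons.add(ExclusionReason.ADULT_ERROR)
    return ExclusionResult(trial_id=spec.trial_id, reasons=frozenset(reasons))


@dataclass(frozen=True)
class ClassifiedSession:
    """A session with alignment and per-trial exclusion results attached."""

    session: Session
    aligned: tuple[AlignedTrial, ...]
    exclusions: tuple[ExclusionResult, ...]

    @property
    def usable(self) -> tuple[AlignedTrial, ...]:
        return tuple(
            t for t, e in zip(self.aligned, self.exclusions) if not e.excluded
        )

    @property
    def n_usable(self) -> int:
        return sum(1 for e in self.exclusions if not e.excluded)


def classify_session(session: Session) -> ClassifiedSession:
    aligned = tuple(align_trial(t.spec, t.looks) for t in session.trials)
    exclusions = tuple(
        classify_trial(t.spec, a) for t, a in zip(session.trials, aligned)
    )
    return ClassifiedSession(session=session, aligned=aligned, exclusions=exclusions)


def filter_subjects(
    classified: Sequence[ClassifiedSession],
) -> tuple[list[ClassifiedSession], list[ClassifiedSession], pd.DataFrame]:
    """Partition subjects by the at-least-half-usable-trials rule.

    The denominator is the experiment's *designed* trial count, not however
    many trials a subject happened to attempt.  Returns (retained, excluded,
    audit) where the audit table has one row per trial: subject_id, trial_id,
    excluded flag, semicolon-joined reasons, and the subject's usable count.
    """
    retained, excluded = [], []
    rows = []
    for cs in classified:
        designed = DESIGN_TRIALS[cs.session.experiment]
        usable = cs.n_usable
        keep = usable >= designed / 2
        (retained if keep else excluded).append(cs)
        for res in cs.exclusions:
            rows.append(
                {
                    "subject_id": cs.session.subject.subject_id,
                    "trial_id": res.trial_id,
                    "excluded": res.excluded,
                    "reasons": ";".join(sorted(r.value for r in res.reasons)),
                    "usable_trial_count": usable,
                    "subject_retained": keep,
                }
            )
    audit = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "trial_id",
            "excluded",
            "reasons",
            "usable_trial_count",
            "subject_retained",
        ],
    )
    return retained, excluded, audit
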