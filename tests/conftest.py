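"""Shared fixtures and builders for constructing sessions by hand."""

from __future__ import annotations

import numpy as np
import pytest

from gazelex.types import (
    AlignedLook,
    AlignedTrial,
    Direction,
    Experiment,
    LookRecord,
    Role,
    Session,
    SubjectMeta,
    Trial,
    TrialSpec,
    Window,
    WindowSummary,
)
from gazelex.windowing import ANALYSIS, ClassifiedSession, classify_trial


def make_spec(
    trial_id: str = "t01",
    experiment: Experiment = Experiment.NOUNS,
    word_pair_id: str = "p1",
    image_pair_index: int = 1,
    target_word: str = "p1_a",
    target_side: Direction = Direction.LEFT,
    target_onset_ms: int = 1000,
    crying: bool = False,
    error: bool = False,
) -> TrialSpec:
    return TrialSpec(
        trial_id=trial_id,
        experiment=experiment,
        word_pair_id=word_pair_id,
        image_pair_index=image_pair_index,
        target_word=target_word,
        target_side=target_side,
        target_onset_ms=target_onset_ms,
        crying_flag=crying,
        error_flag=error,
    )


def aligned(*role_spans, spec: TrialSpec | None = None) -> AlignedTrial:
    """Build an AlignedTrial from (role, onset, offset) triples."""
    spec = spec or make_spec()
    looks = tuple(AlignedLook(role=r, onset_ms=a, offset_ms=b) for r, a, b in role_spans)
    return AlignedTrial(spec=spec, looks=looks)


def summary(
    target_ms: float, distractor_ms: float, away_ms: float, window: Window = ANALYSIS
) -> WindowSummary:
    return WindowSummary(
        trial_id="t", window=window, target_ms=target_ms,
        distractor_ms=distractor_ms, away_ms=away_ms,
    )


def full_design_specs(
    subject_id: str = "s01",
    experiment: Experiment = Experiment.NOUNS,
    n_pairs: int = 8,
    onset_ms: int = 1000,
) -> list[TrialSpec]:
    """A complete balanced manifest: n_pairs x 2 image-pairs x 2 targets."""
    specs = []
    k = 0
    for p in range(1, n_pairs + 1):
        pid = f"p{p}"
        for img in (1, 2):
            for suffix in ("a", "b"):
                k += 1
                specs.append(
                    make_spec(
                        trial_id=f"{subject_id}_t{k:02d}",
                        experiment=experiment,
                        word_pair_id=pid,
                        image_pair_index=img,
                        target_word=f"{pid}_{suffix}",
                        target_side=Direction.LEFT if k % 2 else Direction.RIGHT,
                        target_onset_ms=(k - 1) * 5000 + onset_ms,
                    )
                )
    return specs


def good_looks(spec: TrialSpec, prop_target: float = 0.6) -> list[LookRecord]:
    """Looks making the trial comfortably usable with a given target proportion."""
    onset = spec.target_onset_ms
    other = (
        Direction.RIGHT if spec.target_side is Direction.LEFT else Direction.LEFT
    )
    t_ms = int(3000 * prop_target)
    looks = [
        # a pre-naming look so NO_PRENAMING_LOOK never fires
        LookRecord(spec.trial_id, spec.target_side, onset + 0, onset + 200),
        LookRecord(spec.trial_id, spec.target_side, onset + 400, onset + 400 + t_ms),
    ]
    if t_ms < 3000:
        looks.append(
            LookRecord(
                spec.trial_id, other, onset + 400 + t_ms, onset + 3400
            )
        )
    return looks


def classified_from_aligned(
    subject: SubjectMeta,
    aligned_trials: list[AlignedTrial],
    force_usable: bool = True,
) -> ClassifiedSession:
    """Wrap hand-built aligned trials into a ClassifiedSession.

    With ``force_usable`` the exclusion rules are bypassed (empty reason sets),
    which lets tests construct minimal gaze patterns without also satisfying
    the minimum-looking rule.
    """
    from gazelex.types import ExclusionResult

    session_trials = tuple(Trial(spec=t.spec, looks=()) for t in aligned_trials)
    session = Session(subject=subject, trials=session_trials)
    if force_usable:
        exclusions = tuple(
            ExclusionResult(trial_id=t.spec.trial_id, reasons=frozenset())
            for t in aligned_trials
        )
    else:
        exclusions = tuple(classify_trial(t.spec, t) for t in aligned_trials)
    return ClassifiedSession(
        session=session, aligned=tuple(aligned_trials), exclusions=exclusions
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240530)
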