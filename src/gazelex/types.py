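"""Core data model for interval-coded infant gaze sessions.

A session is one infant's visit: a trial manifest (what was on screen, which
image was named, when) plus the manually coded looks (LEFT / RIGHT / AWAY with
onset and offset on the session clock, in integer milliseconds).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

class Direction(str, enum.Enum):
    """Screen-frame gaze direction as coded from video."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"
    AWAY = "AWAY"


class Role(str, enum.Enum):
    """Trial-frame gaze role after relabeling by target side."""

    TARGET = "TARGET"
    DISTRACTOR = "DISTRACTOR"
    AWAY = "AWAY"


class Experiment(str, enum.Enum):
    NOUNS = "NOUNS"
    HONORIFICS = "HONORIFICS"


#: Designed number of test trials per subject, by experiment
#: (8 word-pairs x 2 image-pairs x 2 targets = 32; 2 pairs x 2 x 2 = 8).
DESIGN_TRIALS = {Experiment.NOUNS: 32, Experiment.HONORIFICS: 8}


class ExclusionReason(str, enum.Enum):
    NO_PRENAMING_LOOK = "NO_PRENAMING_LOOK"
    CRYING = "CRYING"
    MIN_LOOKING = "MIN_LOOKING"
    ADULT_ERROR = "ADULT_ERROR"


@dataclass(frozen=True)
class LookRecord:
    """One coded look: direction over the half-open span [onset, offset) ms."""

    trial_id: str
    direction: Direction
    onset_ms: int
    offset_ms: int

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError(
                f"look in trial {self.trial_id!r}: offset_ms ({self.offset_ms}) "
                f"must exceed onset_ms ({self.onset_ms})"
            )
        if self.onset_ms < 0:
            raise ValueError(f"look in trial {self.trial_id!r}: negative onset_ms")

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class TrialSpec:
    """Design and event information for one trial."""

    trial_id: str
    experiment: Experiment
    word_pair_id: str
    image_pair_index: int  # 1 or 2
    target_word: str
    target_side: Direction  # LEFT or RIGHT
    target_onset_ms: int
    crying_flag: bool = False
    error_flag: bool = False

    def __post_init__(self) -> None:
        if self.image_pair_index not in (1, 2):
            raise ValueError(
                f"trial {self.trial_id!r}: image_pair_index must be 1 or 2, "
                f"got {self.image_pair_index}"
            )
        if self.target_side is Direction.AWAY:
            raise ValueError(f"trial {self.trial_id!r}: target_side must be LEFT or RIGHT")
        if self.target_onset_ms < 0:
            raise ValueError(f"trial {self.trial_id!r}: negative target_onset_ms")


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    age_months: float

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValueError(f"subject {self.subject_id!r}: age_months must be positive")


@dataclass(frozen=True)
class Trial:
    """A trial's spec together with its coded looks (possibly none)."""

    spec: TrialSpec
    looks: tuple[LookRecord, ...]

    def __post_init__(self) -> None:
        for lk in self.looks:
            if lk.trial_id != self.spec.trial_id:
                raise ValueError(
                    f"look trial_id {lk.trial_id!r} does not match spec "
                    f"{self.spec.trial_id!r}"
                )


@dataclass(frozen=True)
class Session:
    """One subject's full visit for one experiment."""

    subject: SubjectMeta
    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        ids = [t.spec.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trial_ids in session: {dupes}")

    @property
    def experiment(self) -> Experiment:
        return self.trials[0].spec.experiment

    def trial(self, trial_id: str) -> Trial:
        for t in self.trials:
            if t.spec.trial_id == trial_id:
                return t
        raise KeyError(trial_id)


# ---------------------------------------------------------------------------
# Windowing products
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedLook:
    """A look re-expressed relative to target-word onset and relabeled."""

    role: Role
    onset_ms: float
    offset_ms: float


@dataclass(frozen=True)
class AlignedTrial:
    spec: TrialSpec
    looks: tuple[AlignedLook, ...]


@dataclass(frozen=True)
class Window:
    """Half-open analysis window [start_ms, end_ms) relative to target onset."""

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError(f"window {self.name!r}: end must exceed start")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class WindowSummary:
    trial_id: str
    window: Window
    target_ms: float
    distractor_ms: float
    away_ms: float

    @property
    def looking_ms(self) -> float:
        """Time on either display (the denominator of looking proportions)."""
        return self.target_ms + self.distractor_ms


@dataclass(frozen=True)
class BinSeries:
    trial_id: str
    window: Window
    bin_ms: float
    states: tuple[Role, ...]

    def count(self, role: Role) -> int:
        return sum(1 for s in self.states if s is role)


@dataclass(frozen=True)
class ExclusionResult:
    trial_id: str
    reasons: frozenset[ExclusionReason]

    @property
    def excluded(self) -> bool:
        return bool(self.reasons)


# ---------------------------------------------------------------------------
# Scoring products
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairScore:
    """Baseline-corrected difference score for one (subject, word-pair)."""

    subject_id: str
    word_pair_id: str
    score: float
    n_image_pairs_used: int
    contributing_trial_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"pair score out of [-1, 1]: {self.score}")
        if self.n_image_pairs_used not in (1, 2):
            raise ValueError("n_image_pairs_used must be 1 or 2")
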