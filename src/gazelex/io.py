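"""Readers and writers for gaze annotations, trial manifests and subject metadata.

The canonical on-disk dialect is a UTF-8 comma-separated table with a header
row.  Coding tools export in many shapes, so look-annotation readers live in a
small registry: ``register_dialect`` lets an adapter translate a native export
into :class:`~gazelex.types.LookRecord` rows without touching the science core.

Canonical columns
-----------------
looks.csv     : [subject_id,] trial_id, direction, onset_ms, offset_ms
manifest.csv  : [subject_id,] trial_id, experiment, word_pair_id,
                image_pair_index, target_word, target_side, target_onset_ms,
                crying_flag, error_flag
subjects.csv  : subject_id, age_months
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import DesignError, FormatError, ValidationError
from .types import (
    Direction,
    Experiment,
    LookRecord,
    Session,
    SubjectMeta,
    Trial,
    TrialSpec,
)

LOOK_COLUMNS = ["trial_id", "direction", "onset_ms", "offset_ms"]
MANIFEST_COLUMNS = [
    "trial_id",
    "experiment",
    "word_pair_id",
    "image_pair_index",
    "target_word",
    "target_side",
    "target_onset_ms",
    "crying_flag",
    "error_flag",
]
SUBJECT_COLUMNS = ["subject_id", "age_months"]

_DIRECTION_CODES = {
    "L": Direction.LEFT,
    "LEFT": Direction.LEFT,
    "R": Direction.RIGHT,
    "RIGHT": Direction.RIGHT,
    "A": Direction.AWAY,
    "AWAY": Direction.AWAY,
    "OFF": Direction.AWAY,
    ".": Direction.AWAY,
}

_TRUE = {"1", "TRUE", "T", "YES", "Y"}
_FALSE = {"0", "FALSE", "F", "NO", "N", ""}

_DIALECTS: dict[str, Callable[[Path], pd.DataFrame]] = {}


def register_dialect(name: str):
    """Register a look-annotation reader returning a canonical-column DataFrame."""

    def deco(fn: Callable[[Path], pd.DataFrame]):
        _DIALECTS[name] = fn
        return fn

    return deco


@register_dialect("canonical")
def _read_canonical(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unparseable file: {exc}") from exc
    return df


def _parse_direction(raw: str, line: int, path: Path) -> Direction:
    code = raw.strip().upper()
    if code not in _DIRECTION_CODES:
        raise FormatError(f"{path}, line {line}: unknown direction code {raw!r}")
    return _DIRECTION_CODES[code]


def _parse_bool(raw: object, line: int, col: str, path: Path) -> bool:
    code = str(raw).strip().upper()
    if code in _TRUE:
        return True
    if code in _FALSE:
        return False
    raise FormatError(f"{path}, line {line}: bad boolean {raw!r} in column {col!r}")


def _parse_int(raw: object, line: int, col: str, path: Path) -> int:
    try:
        return int(float(str(raw)))
    except ValueError:
        raise FormatError(f"{path}, line {line}: bad integer {raw!r} in column {col!r}")


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def check_no_overlap(records: Sequence[LookRecord]) -> None:
    """Raise if looks within any trial overlap (records need not be sorted)."""
    by_trial: dict[str, list[LookRecord]] = defaultdict(list)
    for rec in records:
        by_trial[rec.trial_id].append(rec)
    for trial_id, recs in by_trial.items():
        recs = sorted(recs, key=lambda r: r.onset_ms)
        for prev, nxt in zip(recs, recs[1:]):
            if nxt.onset_ms < prev.offset_ms:
                raise ValidationError(
                    f"overlapping looks in trial {trial_id!r}: "
                    f"[{prev.onset_ms}, {prev.offset_ms}) and "
                    f"[{nxt.onset_ms}, {nxt.offset_ms})"
                )


def read_look_annotations(
    path: str | Path, dialect: str = "canonical"
) -> list[LookRecord]:
    """Read interval-coded looks, sorted by (trial_id, onset_ms).

    Gaps between looks are legitimate (the infant was looking away, i.e.
    off-display); overlapping looks within a trial are a coding error and
    raise :class:`ValidationError` naming the trial.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    if dialect not in _DIALECTS:
        raise FormatError(
            f"unknown annotation dialect {dialect!r}; registered: {sorted(_DIALECTS)}"
        )
    df = _DIALECTS[dialect](path)
    _check_columns(df, LOOK_COLUMNS, path)

    records: list[LookRecord] = []
    bad_rows: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            direction = _parse_direction(getattr(row, "direction"), line, path)
            onset = _parse_int(getattr(row, "onset_ms"), line, "onset_ms", path)
            offset = _parse_int(getattr(row, "offset_ms"), line, "offset_ms", path)
            records.append(
                LookRecord(str(getattr(row, "trial_id")), direction, onset, offset)
            )
        except (FormatError, ValueError) as exc:
            bad_rows.append(f"line {line}: {exc}")
    if bad_rows:
        raise ValidationError(
            f"{path}: {len(bad_rows)} malformed row(s):\n  " + "\n  ".join(bad_rows)
        )
    check_no_overlap(records)
    records.sort(key=lambda r: (r.trial_id, r.onset_ms))
    return records


def validate_design(specs: Sequence[TrialSpec], subject: str = "?") -> None:
    """Check that each (word_pair, image_pair) occurs exactly twice, once per target."""
    counts = Counter((s.word_pair_id, s.image_pair_index) for s in specs)
    for (pair, img), n in sorted(counts.items()):
        if n != 2:
            raise DesignError(
                f"subject {subject}: (word_pair {pair!r}, image_pair {img}) occurs "
                f"{n} time(s); expected exactly 2 (one per target)"
            )
        targets = {
            s.target_word
            for s in specs
            if s.word_pair_id == pair and s.image_pair_index == img
        }
        if len(targets) != 2:
            raise DesignError(
                f"subject {subject}: (word_pair {pair!r}, image_pair {img}) does not "
                f"have two distinct targets (saw {sorted(targets)})"
            )


def _specs_from_frame(df: pd.DataFrame, path: Path) -> list[TrialSpec]:
    specs = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        exp_raw = str(getattr(row, "experiment")).strip().upper()
        try:
            experiment = Experiment(exp_raw)
        except ValueError:
            raise FormatError(f"{path}, line {line}: unknown experiment {exp_raw!r}")
        side = _parse_direction(str(getattr(row, "target_side")), line, path)
        try:
            specs.append(
                TrialSpec(
                    trial_id=str(getattr(row, "trial_id")),
                    experiment=experiment,
                    word_pair_id=str(getattr(row, "word_pair_id")),
                    image_pair_index=_parse_int(
                        getattr(row, "image_pair_index"), line, "image_pair_index", path
                    ),
                    target_word=str(getattr(row, "target_word")),
                    target_side=side,
                    target_onset_ms=_parse_int(
                        getattr(row, "target_onset_ms"), line, "target_onset_ms", path
                    ),
                    crying_flag=_parse_bool(
                        getattr(row, "crying_flag"), line, "crying_flag", path
                    ),
                    error_flag=_parse_bool(
                        getattr(row, "error_flag"), line, "error_flag", path
                    ),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}, line {line}: {exc}") from exc
    return specs


def read_trial_manifest(path: str | Path) -> list[TrialSpec]:
    """Read a single-subject trial manifest; file order is presentation order."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, MANIFEST_COLUMNS, path)
    specs = _specs_from_frame(df, path)
    validate_design(specs)
    return specs


def read_subjects(path: str | Path) -> list[SubjectMeta]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    df = pd.read_csv(path, dtype={"subject_id": str, "age_months": float})
    _check_columns(df, SUBJECT_COLUMNS, path)
    metas = []
    for row in df.itertuples(index=False):
        meta = SubjectMeta(str(row.subject_id), float(row.age_months))
        if not 3.0 <= meta.age_months <= 24.0:
            warnings.warn(
                f"subject {meta.subject_id}: age {meta.age_months:.2f} mo outside "
                f"the plausible infant range (3-24 mo)",
                stacklevel=2,
            )
        metas.append(meta)
    return metas


def assemble_session(
    meta: SubjectMeta,
    specs: Sequence[TrialSpec],
    looks: Sequence[LookRecord],
) -> Session:
    """Join a subject's manifest with their coded looks into a Session.

    Trials with no looks are retained: an infant who never fixated the
    displays is exactly what the exclusion rules are there to catch.
    """
    validate_design(specs, subject=meta.subject_id)
    spec_ids = {s.trial_id for s in specs}
    if len(spec_ids) != len(specs):
        raise ValidationError(f"subject {meta.subject_id}: duplicate trial_ids in manifest")
    orphans = sorted({lk.trial_id for lk in looks} - spec_ids)
    if orphans:
        raise ValidationError(
            f"subject {meta.subject_id}: look records reference unknown trial_ids {orphans}"
        )
    check_no_overlap(looks)
    by_trial: dict[str, list[LookRecord]] = defaultdict(list)
    for lk in looks:
        by_trial[lk.trial_id].append(lk)
    trials = tuple(
        Trial(
            spec=s,
            looks=tuple(sorted(by_trial.get(s.trial_id, []), key=lambda r: r.onset_ms)),
        )
        for s in specs
    )
    return Session(subject=meta, trials=trials)


# ---------------------------------------------------------------------------
# Study-level (multi-subject) files, as written by the simulator and CLI
# ---------------------------------------------------------------------------


def load_study(directory: str | Path) -> list[Session]:
    """Load subjects.csv + manifest.csv + looks.csv from a study directory."""
    directory = Path(directory)
    metas = read_subjects(directory / "subjects.csv")

    mpath = directory / "manifest.csv"
    mdf = pd.read_csv(mpath, dtype=str, keep_default_na=False)
    _check_columns(mdf, ["subject_id"] + MANIFEST_COLUMNS, mpath)

    lpath = directory / "looks.csv"
    ldf = pd.read_csv(lpath, dtype=str, keep_default_na=False)
    _check_columns(ldf, ["subject_id"] + LOOK_COLUMNS, lpath)

    sessions = []
    for meta in metas:
        specs = _specs_from_frame(
            mdf[mdf["subject_id"] == meta.subject_id], mpath
        )
        sub_looks = ldf[ldf["subject_id"] == meta.subject_id]
        looks = []
        for i, row in enumerate(sub_looks.itertuples(index=False)):
            looks.append(
                LookRecord(
                    str(row.trial_id),
                    _parse_direction(str(row.direction), i + 2, lpath),
                    _parse_int(row.onset_ms, i + 2, "onset_ms", lpath),
                    _parse_int(row.offset_ms, i + 2, "offset_ms", lpath),
                )
            )
        sessions.append(assemble_session(meta, specs, looks))
    return sessions


def write_study(sessions: Iterable[Session], directory: str | Path) -> None:
    """Write sessions to the canonical three-file study layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sub_rows, man_rows, look_rows = [], [], []
    for sess in sessions:
        sub_rows.append(
            {"subject_id": sess.subject.subject_id, "age_months": sess.subject.age_months}
        )
        for trial in sess.trials:
            s = trial.spec
            man_rows.append(
                {
                    "subject_id": sess.subject.subject_id,
                    "trial_id": s.trial_id,
                    "experiment": s.experiment.value,
                    "word_pair_id": s.word_pair_id,
                    "image_pair_index": s.image_pair_index,
                    "target_word": s.target_word,
                    "target_side": s.target_side.value,
                    "target_onset_ms": s.target_onset_ms,
                    "crying_flag": int(s.crying_flag),
                    "error_flag": int(s.error_flag),
                }
            )
            for lk in trial.looks:
                look_rows.append(
                    {
                        "subject_id": sess.subject.subject_id,
                        "trial_id": lk.trial_id,
                        "direction": lk.direction.value,
                        "onset_ms": lk.onset_ms,
                        "offset_ms": lk.offset_ms,
                    }
                )
    pd.DataFrame(sub_rows, columns=SUBJECT_COLUMNS).to_csv(
        directory / "subjects.csv", index=False
    )
    pd.DataFrame(man_rows, columns=["subject_id"] + MANIFEST_COLUMNS).to_csv(
        directory / "manifest.csv", index=False
    )
    pd.DataFrame(look_rows, columns=["subject_id"] + LOOK_COLUMNS).to_csv(
        directory / "looks.csv", index=False
    )
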