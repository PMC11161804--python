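"""Pair-based, baseline-corrected difference scores.

For an image-pair presented twice (each image named once), the score for a
designated image is

    P(look image | image named)  -  P(look image | other image named)

with proportions taken over on-display time only (AWAY time never enters the
denominator).  Under that convention the score does not depend on which image
of the pair is designated: writing p1, p2 for the *target*-looking proportions
on the two trials, the score is p1 + p2 - 1 either way.  A word-pair score is
the mean over its image-pairs that have both presentations usable (1 or 2);
it is missing — not zero — when neither image-pair is complete.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedProportionError
from .types import AlignedTrial, PairScore, WindowSummary
from .windowing import ANALYSIS, ClassifiedSession, summarize_window


def target_proportion(summary: WindowSummary) -> float:
    """Proportion of on-display looking directed to the target."""
    denom = summary.target_ms + summary.distractor_ms
    if denom <= 0:
        raise UndefinedProportionError(
            f"trial {summary.trial_id!r}: no on-display looking in window "
            f"{summary.window.name}; the minimum-looking exclusion should have "
            f"removed this trial"
        )
    return summary.target_ms / denom


def image_pair_score(
    when_target: WindowSummary, when_distractor: WindowSummary
) -> float:
    """Difference score for one image-pair from its two presentations.

    ``when_target``: the trial on which the designated image was named.
    ``when_distractor``: the matched trial on which the other image was named,
    so the designated image was the distractor there.
    """
    p_named = target_proportion(when_target)
    p_unnamed_trial = target_proportion(when_distractor)
    return p_named - (1.0 - p_unnamed_trial)


def word_pair_score(
    subject_id: str,
    word_pair_id: str,
    image_pair_scores: Mapping[int, Optional[float]],
    contributing_trial_ids: Sequence[str] = (),
) -> Optional[PairScore]:
    """Mean over complete image-pairs; None when no image-pair is complete."""
    defined = {k: v for k, v in image_pair_scores.items() if v is not None}
    if not defined:
        return None
    return PairScore(
        subject_id=subject_id,
        word_pair_id=word_pair_id,
        score=float(np.mean(list(defined.values()))),
        n_image_pairs_used=len(defined),
        contributing_trial_ids=tuple(contributing_trial_ids),
    )


def score_session(classified: ClassifiedSession) -> list[PairScore]:
    """All defined word-pair scores for one subject, from usable trials only."""
    usable: dict[tuple[str, int], list[AlignedTrial]] = defaultdict(list)
    for trial in classified.usable:
        key = (trial.spec.word_pair_id, trial.spec.image_pair_index)
        usable[key].append(trial)

    by_pair: dict[str, dict[int, Optional[float]]] = defaultdict(dict)
    trials_used: dict[str, list[str]] = defaultdict(list)
    pair_ids_in_order: list[str] = []
    for trial in classified.aligned:
        pid = trial.spec.word_pair_id
        if pid not in pair_ids_in_order:
            pair_ids_in_order.append(pid)

    for (pid, img), trials in usable.items():
        if len(trials) != 2:
            by_pair[pid].setdefault(img, None)
            continue
        a, b = trials
        # designate trial a's target image; trial b is its distractor trial
        score = image_pair_score(
            summarize_window(a, ANALYSIS), summarize_window(b, ANALYSIS)
        )
        by_pair[pid][img] = score
        trials_used[pid] += [a.spec.trial_id, b.spec.trial_id]

    subject_id = classified.session.subject.subject_id
    out = []
    for pid in pair_ids_in_order:
        ps = word_pair_score(subject_id, pid, by_pair.get(pid, {}), trials_used[pid])
        if ps is not None:
            out.append(ps)
    return out


@dataclass(frozen=True)
class ScoreTable:
    """All pair scores of a study plus their marginal means.

    Item means average over the subjects with a defined score for that pair;
    subject means average over that subject's defined pairs.  Both marginals
    are recomputable from ``rows`` by a plain group-by.
    """

    rows: pd.DataFrame  # subject_id, word_pair_id, score, n_image_pairs_used

    @property
    def item_means(self) -> pd.Series:
        return self.rows.groupby("word_pair_id", sort=True)["score"].mean()

    @property
    def subject_means(self) -> pd.Series:
        return self.rows.groupby("subject_id", sort=True)["score"].mean()

    @property
    def grand_item_mean(self) -> float:
        return float(self.item_means.mean())

    @property
    def grand_subject_mean(self) -> float:
        return float(self.subject_means.mean())


def aggregate_scores(scores: Sequence[PairScore]) -> ScoreTable:
    if not scores:
        raise ValueError("aggregate_scores requires at least one defined PairScore")
    rows = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scores],
            "word_pair_id": [s.word_pair_id for s in scores],
            "score": [s.score for s in scores],
            "n_image_pairs_used": [s.n_image_pairs_used for s in scores],
        }
    )
    return ScoreTable(rows=rows)


def score_study(classified_sessions: Sequence[ClassifiedSession]) -> ScoreTable:
    all_scores: list[PairScore] = []
    for cs in classified_sessions:
        all_scores.extend(score_session(cs))
    return aggregate_scores(all_scores)
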