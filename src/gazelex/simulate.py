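"""Synthetic looking-while-listening sessions with known ground truth.

The generator emulates the data-generating process the analysis models
assume: an infant's gaze over a trial is a first-order Markov chain over
{TARGET, DISTRACTOR, AWAY} on a 20 ms grid.  At each bin the chain stays in
its current state with probability ``stay_prob`` (gaze persistence —
fixations are long relative to a bin); otherwise it redraws a state: AWAY
with probability ``away_prob``, else TARGET with probability
``logistic(eta)``.  Because the redraw distribution is also the chain's
stationary distribution, the marginal per-bin odds of target looking are
exactly ``exp(eta)`` regardless of persistence.

Before the word can have been processed (bins starting < 367 ms after
target-word onset) eta is only the baseline image preference; from 367 ms on
it adds the knowledge effect, subject and item random effects, and the age
slope:

    eta_pre  = pref(target image) - pref(distractor image)
    eta_post = eta_pre + beta + b_subject + u_item + age_slope * z_age

Crying and experimenter-error contamination are Bernoulli per trial.  All
randomness flows from a single integer seed; the same seed reproduces the
study byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .types import (
    Direction,
    Experiment,
    LookRecord,
    Role,
    Session,
    SubjectMeta,
    Trial,
    TrialSpec,
)

#: Word-pair inventories by design.  The honorific inventory uses the four
#: Tseltal greeting terms, paired old-woman/young-man and old-man/young-woman.
NOUN_PAIRS: dict[str, tuple[str, str]] = {
    f"noun{k}": (f"noun{k}_a", f"noun{k}_b") for k in range(1, 9)
}
HONORIFIC_PAIRS: dict[str, tuple[str, str]] = {
    "hon1": ("metik", "tatil"),
    "hon2": ("tatik", "kantsil"),
}

TRIAL_SPACING_MS = 5000  # session-clock gap between successive trial onsets
PRE_ROLL_MS = 1000  # coded span starts this long before target-word onset


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings.

    Defaults mirror the field study's conditions: 21 infants aged roughly
    5.3-15.4 months, the 32-trial nouns design, a post-naming knowledge
    effect of 0.25 on the logit scale (odds ratio ~1.28), and moderate
    subject/item/image heterogeneity.
    """

    n_subjects: int = 21
    age_range_months: tuple[float, float] = (5.3, 15.4)
    design: Experiment = Experiment.NOUNS
    knowledge_effect: float = 0.25
    subject_effect_sd: float = 0.3
    item_effect_sd: float = 0.2
    age_slope: float = 0.08
    baseline_image_pref_sd: float = 0.3
    away_prob: float = 0.25
    stay_prob: float = 0.9
    crying_prob: float = 0.05
    error_prob: float = 0.03
    bin_ms: float = 20.0
    trial_span_ms: tuple[float, float] = (-1000.0, 3500.0)
    post_onset_boundary_ms: float = 367.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("away_prob", "stay_prob", "crying_prob", "error_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.stay_prob >= 1.0:
            raise ValueError("stay_prob must be < 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")

    @property
    def word_pairs(self) -> dict[str, tuple[str, str]]:
        return NOUN_PAIRS if self.design is Experiment.NOUNS else HONORIFIC_PAIRS


@dataclass(frozen=True)
class SimTruth:
    """Realized latent quantities, kept for parameter-recovery scoring."""

    knowledge_effect: float
    age_slope: float
    subject_effects: dict[str, float]
    item_effects: dict[str, float]
    image_prefs: dict[tuple[str, int], float]
    ages_months: dict[str, float]
    z_ages: dict[str, float]


def _simulate_bins(
    rng: np.random.Generator,
    n_bins: int,
    eta_by_bin: np.ndarray,
    away_prob: float,
    stay_prob: float,
) -> np.ndarray:
    """Markov chain over role codes 0=TARGET, 1=DISTRACTOR, 2=AWAY.

    Between redraw events the state is constant, so the whole chain is the
    redraw state at the most recent redraw bin — which vectorizes.
    """
    redraw_mask = rng.random(n_bins) >= stay_prob
    redraw_mask[0] = True
    away = rng.random(n_bins) < away_prob
    on_target = rng.random(n_bins) < expit(eta_by_bin)
    redraw_state = np.where(away, 2, np.where(on_target, 0, 1)).astype(np.int8)
    last_redraw = np.maximum.accumulate(
        np.where(redraw_mask, np.arange(n_bins), -1)
    )
    return redraw_state[last_redraw]


def _bins_to_looks(
    states: np.ndarray,
    spec: TrialSpec,
    bin_ms: float,
    span_start_ms: float,
) -> list[LookRecord]:
    """Merge runs of on-display bins into LookRecords; AWAY becomes a gap."""
    role_to_dir = {
        0: spec.target_side,
        1: Direction.LEFT if spec.target_side is Direction.RIGHT else Direction.RIGHT,
    }
    looks = []
    k = 0
    n = len(states)
    onset0 = spec.target_onset_ms  # session clock
    while k < n:
        if states[k] == 2:
            k += 1
            continue
        j = k
        while j < n and states[j] == states[k]:
            j += 1
        looks.append(
            LookRecord(
                trial_id=spec.trial_id,
                direction=role_to_dir[int(states[k])],
                onset_ms=int(onset0 + span_start_ms + k * bin_ms),
                offset_ms=int(onset0 + span_start_ms + j * bin_ms),
            )
        )
        k = j
    return looks


def _build_manifest(
    config: SimConfig, subject_id: str, rng: np.random.Generator
) -> list[TrialSpec]:
    cells = []
    for pair_id, words in config.word_pairs.items():
        for img in (1, 2):
            for target in words:
                cells.append((pair_id, img, target))
    order = rng.permutation(len(cells))
    specs = []
    for k, idx in enumerate(order):
        pair_id, img, target = cells[idx]
        trial_start = k * TRIAL_SPACING_MS
        specs.append(
            TrialSpec(
                trial_id=f"{subject_id}_t{k + 1:02d}",
                experiment=config.design,
                word_pair_id=pair_id,
                image_pair_index=img,
                target_word=target,
                target_side=Direction.LEFT if rng.random() < 0.5 else Direction.RIGHT,
                target_onset_ms=trial_start + PRE_ROLL_MS,
                crying_flag=bool(rng.random() < config.crying_prob),
                error_flag=bool(rng.random() < config.error_prob),
            )
        )
    return specs


def simulate_trial(
    config: SimConfig,
    spec: TrialSpec,
    subject_effect: float,
    item_effects: dict[str, float],
    image_prefs: dict[tuple[str, int], float],
    z_age: float,
    rng: np.random.Generator,
) -> list[LookRecord]:
    """Simulate the gaze record for one already-specified trial."""
    words = config.word_pairs[spec.word_pair_id]
    other = words[0] if spec.target_word == words[1] else words[1]
    pref = (
        image_prefs[(spec.target_word, spec.image_pair_index)]
        - image_prefs[(other, spec.image_pair_index)]
    )
    eta_pre = pref
    eta_post = (
        pref
        + config.knowledge_effect
        + subject_effect
        + item_effects[spec.word_pair_id]
        + config.age_slope * z_age
    )
    lo, hi = config.trial_span_ms
    n_bins = int(round((hi - lo) / config.bin_ms))
    rel_starts = lo + config.bin_ms * np.arange(n_bins)
    eta_by_bin = np.where(
        rel_starts >= config.post_onset_boundary_ms, eta_post, eta_pre
    )
    states = _simulate_bins(
        rng, n_bins, eta_by_bin, config.away_prob, config.stay_prob
    )
    return _bins_to_looks(states, spec, config.bin_ms, lo)


def simulate_study(config: SimConfig) -> tuple[list[Session], SimTruth]:
    """Simulate a full cohort; returns the sessions and the realized truth."""
    rng = np.random.default_rng(config.seed)
    subject_ids = [f"s{k + 1:02d}" for k in range(config.n_subjects)]
    lo_age, hi_age = config.age_range_months
    ages = {s: float(rng.uniform(lo_age, hi_age)) for s in subject_ids}
    age_arr = np.array(list(ages.values()))
    age_sd = age_arr.std(ddof=1) if len(age_arr) > 1 else 1.0
    z_ages = {
        s: float((a - age_arr.mean()) / age_sd) if age_sd > 0 else 0.0
        for s, a in ages.items()
    }
    subject_effects = {
        s: float(rng.normal(0.0, config.subject_effect_sd)) for s in subject_ids
    }
    item_effects = {
        p: float(rng.normal(0.0, config.item_effect_sd)) for p in config.word_pairs
    }
    image_prefs = {
        (word, img): float(rng.normal(0.0, config.baseline_image_pref_sd))
        for pair in config.word_pairs.values()
        for word in pair
        for img in (1, 2)
    }

    sessions = []
    for sid in subject_ids:
        specs = _build_manifest(config, sid, rng)
        trials = []
        for spec in specs:
            looks = simulate_trial(
                config,
                spec,
                subject_effects[sid],
                item_effects,
                image_prefs,
                z_ages[sid],
                rng,
            )
            trials.append(Trial(spec=spec, looks=tuple(looks)))
        sessions.append(
            Session(subject=SubjectMeta(sid, ages[sid]), trials=tuple(trials))
        )
    truth = SimTruth(
        knowledge_effect=config.knowledge_effect,
        age_slope=config.age_slope,
        subject_effects=subject_effects,
        item_effects=item_effects,
        image_prefs=image_prefs,
        ages_months=ages,
        z_ages=z_ages,
    )
    return sessions, truth


def expected_difference_score(
    config: SimConfig, n_replicates: int = 2000, seed: Optional[int] = None
) -> float:
    """Long-run expectation of the pair-based difference score under the
    gaze process, by brute-force simulation of matched trial pairs."""
    from .scoring import score_study
    from .windowing import classify_session

    cfg = replace(
        config,
        n_subjects=max(4, min(config.n_subjects, 8)),
        crying_prob=0.0,
        error_prob=0.0,
        seed=config.seed if seed is None else seed,
    )
    scores = []
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max(1, n_replicates // (cfg.n_subjects * 8))):
        sessions, _ = simulate_study(replace(cfg, seed=int(rng.integers(2**31))))
        classified = [classify_session(s) for s in sessions]
        table = score_study(classified)
        scores.extend(table.rows["score"].tolist())
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Parameter-recovery scoring
# ---------------------------------------------------------------------------


def recovery_report(
    truths: Sequence[SimTruth],
    fits: Sequence["GlmmResult"],  # noqa: F821 - forward ref to glmm
    mean_scores: Optional[Sequence[float]] = None,
    expected_score: Optional[float] = None,
) -> dict:
    """Score parameter recovery over replicate (truth, fit) pairs.

    Reports bias and RMSE of the phase coefficient (logit scale), CI coverage
    of the true phase OR, the mean correlation between fitted and true item
    effects, and — when mean difference scores and their process expectation
    are supplied — the score bias against that expectation.
    """
    if len(truths) != len(fits):
        raise ValueError("truths and fits must pair up one-to-one")
    errs, covers, item_corrs = [], [], []
    for truth, fit in zip(truths, fits):
        idx = fit.terms.index("phase_post")
        beta_hat = float(fit.coef[idx])
        errs.append(beta_hat - truth.knowledge_effect)
        true_or = float(np.exp(truth.knowledge_effect))
        covers.append(
            bool(fit.or_ci_low[idx] <= true_or <= fit.or_ci_high[idx])
        )
        if fit.ranef_item and len(fit.ranef_item) >= 3:
            items = sorted(set(truth.item_effects) & set(fit.ranef_item))
            tv = np.array([truth.item_effects[i] for i in items])
            fv = np.array([fit.ranef_item[i] for i in items])
            if tv.std() > 0 and fv.std() > 0:
                item_corrs.append(float(np.corrcoef(tv, fv)[0, 1]))
    errs = np.asarray(errs)
    report = {
        "n_replicates": len(errs),
        "phase_coef_bias": float(errs.mean()),
        "phase_coef_rmse": float(np.sqrt((errs**2).mean())),
        "phase_or_bias": float(np.mean(np.exp(errs + truths[0].knowledge_effect))
                               - np.exp(truths[0].knowledge_effect)),
        "ci_coverage": float(np.mean(covers)),
        "item_effect_corr": float(np.mean(item_corrs)) if item_corrs else None,
    }
    if mean_scores is not None and expected_score is not None:
        ms = np.asarray(mean_scores, dtype=float)
        report["mean_score"] = float(ms.mean())
        report["expected_score"] = float(expected_score)
        report["score_bias"] = float(ms.mean() - expected_score)
    return report
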