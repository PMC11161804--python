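"""Alignment, window summaries, binning, and exclusion rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazelex.errors import GazelexError
from gazelex.types import (
    AlignedLook,
    Direction,
    ExclusionReason,
    Experiment,
    LookRecord,
    Role,
    SubjectMeta,
    Window,
)
from gazelex import io
from gazelex.windowing import (
    ANALYSIS,
    PRENAMING,
    align_trial,
    bin_window,
    classify_session,
    classify_trial,
    filter_subjects,
    summarize_window,
)

from conftest import aligned, full_design_specs, good_looks, make_spec


class TestAlign:
    def test_side_match_becomes_target(self):
        spec = make_spec(target_side=Direction.LEFT, target_onset_ms=1000)
        look = LookRecord("t01", Direction.LEFT, 1200, 1500)
        (al,) = align_trial(spec, [look]).looks
        assert al == AlignedLook(Role.TARGET, 200, 500)

    def test_side_mismatch_becomes_distractor(self):
        spec = make_spec(target_side=Direction.RIGHT, target_onset_ms=1000)
        look = LookRecord("t01", Direction.LEFT, 1200, 1500)
        (al,) = align_trial(spec, [look]).looks
        assert al == AlignedLook(Role.DISTRACTOR, 200, 500)

    def test_look_spanning_onset_is_not_split(self):
        spec = make_spec(target_side=Direction.LEFT, target_onset_ms=1000)
        look = LookRecord("t01", Direction.LEFT, 800, 1400)
        (al,) = align_trial(spec, [look]).looks
        assert (al.onset_ms, al.offset_ms) == (-200, 400)

    def test_empty_looks_allowed(self):
        assert align_trial(make_spec(), []).looks == ()


class TestSummarize:
    def test_full_window_target_look(self):
        t = aligned((Role.TARGET, 367, 3500))
        s = summarize_window(t, ANALYSIS)
        assert (s.target_ms, s.distractor_ms, s.away_ms) == (3133, 0, 0)

    def test_no_looks_all_away(self):
        s = summarize_window(aligned(), ANALYSIS)
        assert s.away_ms == ANALYSIS.duration_ms

    def test_clipping_to_window(self):
        t = aligned((Role.TARGET, 0, 1000), (Role.DISTRACTOR, 1000, 2000))
        s = summarize_window(t, ANALYSIS)
        # clip to [367, 3500): target [367, 1000) = 633, distractor [1000, 2000) = 1000
        assert (s.target_ms, s.distractor_ms) == (633, 1000)
        assert s.away_ms == pytest.approx(3133 - 633 - 1000)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_conservation_on_random_trials(self, data):
        """Role durations always sum exactly to the window duration."""
        n = data.draw(st.integers(0, 8))
        spans = []
        cursor = data.draw(st.integers(-800, 200))
        for _ in range(n):
            gap = data.draw(st.integers(0, 400))
            dur = data.draw(st.integers(1, 1200))
            role = data.draw(st.sampled_from(list(Role)))
            spans.append((role, cursor + gap, cursor + gap + dur))
            cursor += gap + dur
        trial = aligned(*spans)
        for window in (PRENAMING, ANALYSIS):
            s = summarize_window(trial, window)
            assert s.target_ms + s.distractor_ms + s.away_ms == pytest.approx(
                window.duration_ms
            )
            assert min(s.target_ms, s.distractor_ms) >= 0


class TestBinning:
    def test_continuous_target_gives_156_bins(self):
        t = aligned((Role.TARGET, 367, 3500))
        series = bin_window(t, ANALYSIS, 20)
        assert len(series.states) == 156
        assert series.count(Role.TARGET) == 156

    def test_no_looks_all_away(self):
        series = bin_window(aligned(), ANALYSIS, 20)
        assert series.count(Role.AWAY) == len(series.states)

    def test_tie_breaks_to_state_at_bin_start(self):
        t = aligned((Role.TARGET, 367, 377), (Role.DISTRACTOR, 377, 387))
        series = bin_window(t, ANALYSIS, 20)
        assert series.states[0] is Role.TARGET

    def test_majority_wins(self):
        t = aligned((Role.TARGET, 367, 374), (Role.DISTRACTOR, 374, 387))
        series = bin_window(t, ANALYSIS, 20)
        assert series.states[0] is Role.DISTRACTOR

    def test_bin_wider_than_window_rejected(self):
        with pytest.raises(GazelexError):
            bin_window(aligned(), PRENAMING, 400)

    def test_fine_bins_converge_to_durations(self):
        """At 1 ms bins, bin-count proportions equal duration proportions."""
        t = aligned((Role.TARGET, 100, 900), (Role.DISTRACTOR, 1200, 2750))
        series = bin_window(t, ANALYSIS, 1)
        s = summarize_window(t, ANALYSIS)
        assert series.count(Role.TARGET) == s.target_ms
        assert series.count(Role.DISTRACTOR) == s.distractor_ms
        assert series.count(Role.AWAY) == s.away_ms


def brute_force_classify(spec, trial):
    """Independent 1 ms-resolution reimplementation of the exclusion rules."""
    ms = np.full(4500, 2, dtype=int)  # rel time -1000..3500 -> index t+1000
    for lk in trial.looks:
        lo = max(int(lk.onset_ms), -1000) + 1000
        hi = min(int(lk.offset_ms), 3500) + 1000
        code = {Role.TARGET: 0, Role.DISTRACTOR: 1, Role.AWAY: 2}[lk.role]
        if hi > lo:
            ms[lo:hi] = code
    pre = ms[1000:1367]
    ana = ms[1367:4500]
    reasons = set()
    if not np.any(pre < 2):
        reasons.add(ExclusionReason.NO_PRENAMING_LOOK)
    if spec.crying_flag:
        reasons.add(ExclusionReason.CRYING)
    if 3 * int(np.sum(ana < 2)) < 3133:
        reasons.add(ExclusionReason.MIN_LOOKING)
    if spec.error_flag:
        reasons.add(ExclusionReason.ADULT_ERROR)
    return frozenset(reasons)


class TestClassify:
    def test_min_looking_threshold(self):
        t = aligned((Role.TARGET, 0, 100), (Role.TARGET, 500, 1500))
        res = classify_trial(make_spec(), t)
        assert res.reasons == {ExclusionReason.MIN_LOOKING}  # 1000 < 3133/3

    def test_multiple_reasons_co_occur(self):
        t = aligned((Role.TARGET, 400, 3500))
        res = classify_trial(make_spec(crying=True), t)
        assert res.reasons == {
            ExclusionReason.CRYING, ExclusionReason.NO_PRENAMING_LOOK,
        }

    def test_boundary_is_strict(self):
        # 1045 ms of looking: 3*1045 = 3135 >= 3133, so retained
        t = aligned((Role.TARGET, 0, 100), (Role.TARGET, 500, 1545))
        res = classify_trial(make_spec(), t)
        assert not res.excluded

    def test_look_spanning_onset_counts_for_prenaming(self):
        t = aligned((Role.TARGET, -500, 50), (Role.TARGET, 400, 3500))
        res = classify_trial(make_spec(), t)
        assert ExclusionReason.NO_PRENAMING_LOOK not in res.reasons

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.data())
    def test_agrees_with_brute_force(self, data):
        n = data.draw(st.integers(0, 6))
        spans = []
        cursor = data.draw(st.integers(-900, 300))
        for _ in range(n):
            gap = data.draw(st.integers(0, 500))
            dur = data.draw(st.integers(1, 1500))
            role = data.draw(st.sampled_from(list(Role)))
            spans.append((role, cursor + gap, cursor + gap + dur))
            cursor += gap + dur
        spec = make_spec(
            crying=data.draw(st.booleans()), error=data.draw(st.booleans())
        )
        trial = aligned(*spans, spec=spec)
        assert classify_trial(spec, trial).reasons == brute_force_classify(spec, trial)


def _session_with_usable(subject_id, n_usable, experiment=Experiment.NOUNS, n_pairs=8):
    specs = full_design_specs(subject_id, experiment=experiment, n_pairs=n_pairs)
    looks = []
    for k, spec in enumerate(specs):
        if k < n_usable:
            looks.extend(good_looks(spec))
    meta = SubjectMeta(subject_id, 10.0)
    return io.assemble_session(meta, specs, looks)


class TestFilterSubjects:
    def test_half_boundary_is_inclusive(self):
        cs = classify_session(_session_with_usable("s01", 16))
        retained, excluded, _ = filter_subjects([cs])
        assert len(retained) == 1 and not excluded

    def test_honorifics_below_half_excluded(self):
        cs = classify_session(
            _session_with_usable("s01", 3, experiment=Experiment.HONORIFICS, n_pairs=2)
        )
        retained, excluded, _ = filter_subjects([cs])
        assert not retained and len(excluded) == 1

    def test_cohort_exclusion_count_and_audit(self):
        usable_counts = [32, 20, 16, 15, 4, 0]
        classified = [
            classify_session(_session_with_usable(f"s{k:02d}", n))
            for k, n in enumerate(usable_counts, start=1)
        ]
        retained, excluded, audit = filter_subjects(classified)
        assert len(excluded) == 3
        assert len(audit) == 6 * 32
        per_subject = audit.groupby("subject_id")["usable_trial_count"].first()
        assert per_subject.tolist() == usable_counts
        # count conservation: every trial is either excluded or usable
        tallies = audit.groupby("subject_id")["excluded"].sum()
        assert (32 - tallies).tolist() == usable_counts
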