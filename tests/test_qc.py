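"""Trial recoding, glitch detection and retrospective filters."""

import dataclasses

import numpy as np
import pytest

from stoprace.events import (
    GoDirection,
    Outcome,
    SubjectDataset,
    TrialRecord,
    TrialType,
)
from stoprace.experiments import CohortSpec
from stoprace.qc import (
    FilterPolicy,
    apply_filters,
    detect_issue3_subjects,
    flag_context_violators,
    recategorize_trials,
)
from stoprace.race import GeneratingModel, ModelKind, RaceParams
from stoprace.tasksim import TaskConfig, simulate_cohort, simulate_session

MODEL = GeneratingModel(
    ModelKind.INDEPENDENT_RACE, RaceParams(mu_go=0.2, mu_stop=0.43, sigma=1.4)
)


def go_trial(responses, coded, direction=GoDirection.LEFT, idx=0):
    first = responses[0][0] if responses else None
    return TrialRecord(
        subject_id="x", run=1, trial_index=idx, trial_type=TrialType.GO,
        go_direction=direction, ssd_ms=None,
        period_rts=(first or 0, 0, 0), responses=tuple(responses),
        coded_outcome=coded,
        go_stim_duration_ms=min(first, 1000) if first is not None else 1000,
        stop_stim_duration_ms=None,
    )


def stop_trial(ssd, responses, coded, idx=0):
    first = responses[0][0] if responses else None
    return TrialRecord(
        subject_id="x", run=1, trial_index=idx, trial_type=TrialType.STOP,
        go_direction=GoDirection.LEFT, ssd_ms=ssd,
        period_rts=(first or 0, 0, 0), responses=tuple(responses),
        coded_outcome=coded,
        go_stim_duration_ms=ssd if first is None else min(first, ssd),
        stop_stim_duration_ms=300 if ssd <= 700 else 1000 - ssd,
    )


class TestRecategorize:
    def test_stop_with_response_at_stimulus_onset_millisecond(self):
        """A response logged at the exact SSD millisecond still counts: the
        trial is an incorrect stop, not a correct one."""
        t = stop_trial(50, [(50, GoDirection.LEFT)], Outcome.CORRECT_STOP)
        ds = recategorize_trials(SubjectDataset("x", [t]))
        assert ds.trials[0].coded_outcome is Outcome.INCORRECT_STOP
        assert ds.trials[0].original_outcome is Outcome.CORRECT_STOP

    def test_first_response_wins_over_later_overwrite(self):
        """A correct first press followed by a wrong later press is a correct
        go trial, undoing the engine's overwrite-with-last-response bug."""
        t = go_trial(
            [(400, GoDirection.LEFT), (900, GoDirection.RIGHT)], Outcome.INCORRECT_GO
        )
        ds = recategorize_trials(SubjectDataset("x", [t]))
        assert ds.trials[0].coded_outcome is Outcome.CORRECT_GO

    def test_no_response_is_omission(self):
        t = go_trial([], Outcome.CORRECT_GO)
        ds = recategorize_trials(SubjectDataset("x", [t]))
        assert ds.trials[0].coded_outcome is Outcome.GO_OMISSION

    def test_button_flip_correction(self):
        t = go_trial([(400, GoDirection.RIGHT)], Outcome.INCORRECT_GO)
        flipped = recategorize_trials(SubjectDataset("x", [t]), button_flip=True)
        assert flipped.trials[0].coded_outcome is Outcome.CORRECT_GO
        plain = recategorize_trials(SubjectDataset("x", [t]), button_flip=False)
        assert plain.trials[0].coded_outcome is Outcome.INCORRECT_GO

    def test_recategorization_is_idempotent(self):
        ds = simulate_session(MODEL, TaskConfig(), 13)
        once = recategorize_trials(ds)
        twice = recategorize_trials(once)
        assert once.trials == twice.trials

    def test_corrects_injected_miscodings_on_a_session(self):
        config = TaskConfig(issue3_rate=0.0)
        ds = simulate_session(MODEL, config, 21)
        injected = sum(t.coded_outcome is not t.truth_outcome for t in ds.trials)
        assert injected > 0  # defaults do inject
        rec = recategorize_trials(ds)
        assert all(t.coded_outcome is t.truth_outcome for t in rec.trials)


class TestIssue3Detector:
    def _glitched(self, seed=3, glitch_at=12, latency=25):
        """Surgically inject the stuck-SSD signature from stop trial
        ``glitch_at`` onward (the detector is index-agnostic)."""
        ds = simulate_session(MODEL, TaskConfig.clean(), seed)
        stops_seen = 0
        out = []
        for t in ds.trials:
            if t.trial_type is TrialType.STOP:
                if stops_seen == glitch_at:
                    t = stop_trial(50, [(latency, GoDirection.LEFT)],
                                   Outcome.INCORRECT_STOP, idx=t.trial_index)
                elif stops_seen > glitch_at:
                    t = stop_trial(0, [(latency, GoDirection.LEFT)],
                                   Outcome.INCORRECT_STOP, idx=t.trial_index)
                stops_seen += 1
            out.append(t)
        return ds.with_trials(out)

    def test_flags_injected_glitch_at_correct_index(self):
        res = detect_issue3_subjects(self._glitched(glitch_at=12))
        assert res.flagged and res.first_glitch_trial == 12

    def test_clean_staircase_not_flagged(self):
        res = detect_issue3_subjects(simulate_session(MODEL, TaskConfig.clean(), 5))
        assert not res.flagged and res.first_glitch_trial is None

    def test_fast_response_without_stuck_tail_not_flagged(self):
        """A one-off sub-50 ms response at SSD 50 is not the glitch unless the
        stuck-at-zero tail follows."""
        ds = simulate_session(MODEL, TaskConfig.clean(), 6)
        stops_seen = 0
        out = []
        for t in ds.trials:
            if t.trial_type is TrialType.STOP:
                if stops_seen == 4:
                    t = stop_trial(50, [(25, GoDirection.LEFT)],
                                   Outcome.INCORRECT_STOP, idx=t.trial_index)
                stops_seen += 1
            out.append(t)
        assert not detect_issue3_subjects(ds.with_trials(out)).flagged

    def test_generator_injection_recovered_exactly(self):
        spec = dataclasses.replace(CohortSpec(), n_subjects=30)
        cohort = simulate_cohort(
            spec, ModelKind.INDEPENDENT_RACE,
            TaskConfig.clean(issue3_rate=0.3), np.random.default_rng(17),
        )
        truth = [ds.metadata["issue3_injected"] for ds in cohort]
        found = [detect_issue3_subjects(ds).flagged for ds in cohort]
        assert found == truth
        assert any(truth)


class TestContextViolators:
    def test_slow_stop_failures_flagged(self):
        trials = [
            stop_trial(100, [(600, GoDirection.RIGHT)], Outcome.INCORRECT_STOP),
            go_trial([(500, GoDirection.LEFT)], Outcome.CORRECT_GO, idx=1),
        ]
        res = flag_context_violators(SubjectDataset("x", trials))
        assert res.flagged
        assert res.mean_stop_failure_rt == 600 and res.mean_go_rt == 500

    def test_independent_race_subject_not_flagged(self):
        """Race censoring: stop failures are the fast tail of the go
        distribution, so the mean stop-failure RT sits below the go mean."""
        ds = simulate_session(MODEL, TaskConfig.clean(), 23)
        res = flag_context_violators(ds)
        assert res.flagged is False
        assert res.mean_stop_failure_rt < res.mean_go_rt

    def test_no_stop_failures_not_evaluable(self):
        trials = [
            stop_trial(100, [], Outcome.CORRECT_STOP),
            go_trial([(500, GoDirection.LEFT)], Outcome.CORRECT_GO, idx=1),
        ]
        assert flag_context_violators(SubjectDataset("x", trials)).flagged is None


class TestFilters:
    def test_ssd0_trials_removed_by_default(self):
        ds = simulate_session(MODEL, TaskConfig.clean(), 31)
        stops = ds.stop_trials()
        n0 = sum(t.ssd_ms == 0 for t in stops)
        # replace the first three trials with SSD-0 stop trials
        doctored = [
            stop_trial(0, [], Outcome.CORRECT_STOP, idx=t.trial_index) if i < 3 else t
            for i, t in enumerate(ds.trials)
        ]
        ds3 = ds.with_trials(doctored)
        policy = FilterPolicy(drop_incomplete=False, drop_context_violators=False)
        filtered, report = apply_filters(ds3, policy)
        assert report["removed"]["ssd0"] == n0 + 3
        assert all(
            not (t.trial_type is TrialType.STOP and t.ssd_ms == 0)
            for t in filtered.trials
        )

    def test_removal_counts_sum_to_size_difference(self):
        ds = simulate_session(MODEL, TaskConfig.clean(), 37)
        policy = FilterPolicy(min_ssd=200, drop_first_k_stop=7)
        filtered, report = apply_filters(ds, policy)
        removed = sum(report["removed"].values())
        assert removed == len(ds.trials) - len(filtered.trials)
        assert filtered.trials == [t for t in ds.trials if t in filtered.trials]

    def test_min_ssd_report_matches_true_fraction(self):
        """The reported short-SSD removal equals a direct recount."""
        ds = simulate_session(MODEL, TaskConfig.clean(), 41)
        stops = ds.stop_trials()
        expect = sum(0 < t.ssd_ms < 200 for t in stops)  # SSD-0 counted separately
        _, report = apply_filters(ds, FilterPolicy(min_ssd=200))
        assert report["removed"]["below_min_ssd"] == expect

    def test_degenerate_subject_removed(self):
        """All stops successful (P(respond|signal)=0) is degenerate performance."""
        trials = [
            go_trial([(500, GoDirection.LEFT)], Outcome.CORRECT_GO, idx=0),
            stop_trial(100, [], Outcome.CORRECT_STOP, idx=1),
            stop_trial(150, [], Outcome.CORRECT_STOP, idx=2),
        ]
        _, report = apply_filters(
            SubjectDataset("x", trials),
            FilterPolicy(drop_incomplete=False, drop_context_violators=False),
        )
        assert report["subject_removed"]
        assert "degenerate_p_respond" in report["subject_removal_reasons"]

    def test_first_k_stop_trials_removed_per_run(self):
        ds = simulate_session(MODEL, TaskConfig.clean(), 43)
        policy = FilterPolicy(
            drop_first_k_stop=15, remove_ssd0=False, remove_ssd_gt700=False
        )
        filtered, report = apply_filters(ds, policy)
        assert report["removed"]["first_k_stop"] == 2 * 15
        per_run = {1: 0, 2: 0}
        for t in filtered.trials:
            if t.trial_type is TrialType.STOP:
                per_run[t.run] += 1
        assert per_run == {1: 15, 2: 15}

    def test_contradictory_policy_rejected(self):
        with pytest.raises(ValueError):
            FilterPolicy(min_ssd=1000)
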