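"""Quality control for stop-signal event data.

Three layers, mirroring the documented flaws of the ABCD task output:

* :func:`recategorize_trials` — recompute every trial's outcome from the
  authoritative response list (a stop trial is a correct stop iff *no*
  overt response was recorded in any period; go outcomes come from the
  *first* response only, with optional flipped-button correction);
* :func:`detect_issue3_subjects` — find the faulty-SSD glitch signature
  (a sub-50 ms response at SSD 50 after which every later stop trial
  repeats that identical latency with SSD stuck at 0);
* :func:`flag_context_violators` and :func:`apply_filters` — the
  retrospective screening rules (severe context-independence violators,
  SSD-0 and SSD>700 stop trials, short-SSD and early-staircase trials,
  incomplete or degenerate subjects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .events import (
    Outcome,
    SubjectDataset,
    TrialRecord,
    TrialType,
    recode_outcome,
)

__all__ = [
    "recategorize_trials",
    "Issue3Result",
    "detect_issue3_subjects",
    "ViolatorResult",
    "flag_context_violators",
    "FilterPolicy",
    "apply_filters",
    "filter_cohort",
]

_GLITCH_SSD_MS = 50


def _true_outcome(trial: TrialRecord, button_flip: bool) -> Outcome:
    """Outcome implied by the response record (first response authoritative)."""
    if trial.trial_type is TrialType.STOP:
        return Outcome.INCORRECT_STOP if trial.responses else Outcome.CORRECT_STOP
    first = trial.first_response
    if first is None:
        return Outcome.GO_OMISSION
    _, choice = first
    if button_flip:
        choice = choice.opposite
    return Outcome.CORRECT_GO if choice is trial.go_direction else Outcome.INCORRECT_GO


def recategorize_trials(
    dataset: SubjectDataset, button_flip: bool | None = None
) -> SubjectDataset:
    """Recompute all coded outcomes from the response lists.

    ``button_flip`` defaults to the dataset's ``metadata['button_flip']``
    flag; when set, recorded go choices are inverted before scoring.  The
    pre-recode coding is preserved in each trial's ``original_outcome``.
    Idempotent.
    """
    if button_flip is None:
        button_flip = bool(dataset.metadata.get("button_flip", False))
    out = []
    for t in dataset.trials:
        correct = _true_outcome(t, button_flip)
        out.append(recode_outcome(t, correct) if correct is not t.coded_outcome else t)
    return dataset.with_trials(out)


class Issue3Result(NamedTuple):
    flagged: bool
    first_glitch_trial: int | None  # index into the stop-trial sequence


def detect_issue3_subjects(dataset: SubjectDataset) -> Issue3Result:
    """Detect the stuck-SSD glitch.

    A subject is flagged iff some stop trial has a recorded response
    faster than 50 ms at SSD 50 and *every* later stop trial repeats that
    identical latency with SSD 0 (at least one such later trial).  Both
    the trigger and the stuck tail are required, so honest poor
    performers are not flagged.
    """
    stops = dataset.stop_trials()
    if len(stops) < 2:
        return Issue3Result(False, None)
    for k, t in enumerate(stops[:-1]):
        rt = t.first_rt
        if t.ssd_ms == _GLITCH_SSD_MS and rt is not None and rt < _GLITCH_SSD_MS:
            tail = stops[k + 1 :]
            if all(s.ssd_ms == 0 and s.first_rt == rt for s in tail):
                return Issue3Result(True, k)
    return Issue3Result(False, None)


class ViolatorResult(NamedTuple):
    flagged: bool | None  # None: not evaluable
    mean_stop_failure_rt: float | None
    mean_go_rt: float | None


def flag_context_violators(dataset: SubjectDataset) -> ViolatorResult:
    """Severe context-independence violation: mean stop-failure RT > mean go RT.

    Means use first-response latencies on the recategorized outcomes (all
    overt go responses; all stop failures).  Subjects without any stop
    failure or any overt go response are reported as not evaluable.
    """
    recoded = recategorize_trials(dataset)
    sf = [
        float(t.first_rt)
        for t in recoded.stop_trials()
        if t.coded_outcome is Outcome.INCORRECT_STOP and t.first_rt is not None
    ]
    go = [float(t.first_rt) for t in recoded.go_trials() if t.first_rt is not None]
    if not sf or not go:
        return ViolatorResult(None, float(np.mean(sf)) if sf else None,
                              float(np.mean(go)) if go else None)
    m_sf, m_go = float(np.mean(sf)), float(np.mean(go))
    return ViolatorResult(m_sf > m_go, m_sf, m_go)


@dataclass(frozen=True)
class FilterPolicy:
    """Retrospective filter toggles.

    Trial-level: drop SSD-0 stop trials, SSD>700 stop trials, stop trials
    below ``min_ssd`` (suggested 200 ms; off by default), and the first
    ``drop_first_k_stop`` staircase trials of each run (suggested 7 or
    15).  Subject-level: drop glitched, severely violating, incomplete,
    and degenerate (P(respond|signal) of 0 or 1) subjects.
    """

    remove_ssd0: bool = True
    remove_ssd_gt700: bool = True
    min_ssd: int | None = None
    drop_first_k_stop: int = 0
    drop_issue3_subjects: bool = True
    drop_context_violators: bool = True
    drop_incomplete: bool = True
    drop_degenerate: bool = True

    def __post_init__(self) -> None:
        if self.min_ssd is not None and not 0 <= self.min_ssd <= 900:
            raise ValueError("min_ssd must be in [0, 900]")
        if self.drop_first_k_stop < 0:
            raise ValueError("drop_first_k_stop must be >= 0")


def apply_filters(
    dataset: SubjectDataset, policy: FilterPolicy | None = None
) -> tuple[SubjectDataset, dict]:
    """Apply a filter policy to one (recategorized) dataset.

    Returns the filtered dataset (empty when the whole subject is
    removed) and a removal report whose per-rule counts sum to the number
    of removed trials.  Surviving records are never modified.
    """
    policy = policy or FilterPolicy()
    report: dict = {
        "subject_id": dataset.subject_id,
        "subject_removed": False,
        "subject_removal_reasons": [],
        "n_input_trials": len(dataset.trials),
        "removed": {
            "ssd0": 0, "ssd_gt700": 0, "below_min_ssd": 0, "first_k_stop": 0,
            "subject_rule": 0,
        },
    }

    reasons = []
    if policy.drop_incomplete and not dataset.complete:
        reasons.append("incomplete")
    if policy.drop_issue3_subjects and detect_issue3_subjects(dataset).flagged:
        reasons.append("issue3")
    if policy.drop_context_violators and flag_context_violators(dataset).flagged:
        reasons.append("context_violator")
    if policy.drop_degenerate:
        stops = dataset.stop_trials()
        if stops:
            p = np.mean(
                [t.coded_outcome is Outcome.INCORRECT_STOP for t in stops]
            )
            if p in (0.0, 1.0):
                reasons.append("degenerate_p_respond")
    if reasons:
        report["subject_removed"] = True
        report["subject_removal_reasons"] = reasons
        report["removed"]["subject_rule"] = len(dataset.trials)
        report["n_output_trials"] = 0
        return dataset.with_trials([]), report

    kept: list[TrialRecord] = []
    stop_seen: dict[int, int] = {}
    for t in dataset.trials:
        if t.trial_type is TrialType.STOP:
            k = stop_seen.get(t.run, 0)
            stop_seen[t.run] = k + 1
            if k < policy.drop_first_k_stop:
                report["removed"]["first_k_stop"] += 1
                continue
            if policy.remove_ssd0 and t.ssd_ms == 0:
                report["removed"]["ssd0"] += 1
                continue
            if policy.remove_ssd_gt700 and t.ssd_ms is not None and t.ssd_ms > 700:
                report["removed"]["ssd_gt700"] += 1
                continue
            if policy.min_ssd is not None and t.ssd_ms is not None and t.ssd_ms < policy.min_ssd:
                report["removed"]["below_min_ssd"] += 1
                continue
        kept.append(t)
    report["n_output_trials"] = len(kept)
    return dataset.with_trials(kept), report


def filter_cohort(
    cohort: list[SubjectDataset], policy: FilterPolicy | None = None
) -> tuple[list[SubjectDataset], list[dict]]:
    """Apply a policy across a cohort; removed subjects are dropped entirely."""
    kept, reports = [], []
    for ds in cohort:
        filtered, rep = apply_filters(ds, policy)
        reports.append(rep)
        if not rep["subject_removed"]:
            kept.append(filtered)
    return kept, reports
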