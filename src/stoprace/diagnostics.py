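"""Descriptive evidence reports over stop-signal event data.

Each report is a pure function of a cohort (a list of
:class:`~stoprace.events.SubjectDataset`) returning plain dictionaries /
DataFrames, so the same battery runs on synthetic or real event tables:

* :func:`context_independence_report` — stop-failure vs go RT and
  accuracy (the primary behavioural test of context independence), plus
  the accuracy-by-SSD curve;
* :func:`sequence_report` — conditional stop probabilities by lag since
  the last stop signal, and post-stop-signal slowing by task quartile;
* :func:`timecourse_report` — stop accuracy and SSD across the 60 stop
  trials of a session (staircase warm-up, run-2 reset);
* :func:`design_summary_report` — go-stimulus duration distributions,
  the SSD histogram, and stop-trial probability.

Confidence intervals are 95% t-intervals across subject-level means
unless noted; per-SSD accuracy uses a pooled normal-approximation
binomial interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .events import Outcome, SubjectDataset, TrialType
from .qc import flag_context_violators, recategorize_trials

__all__ = [
    "context_independence_report",
    "sequence_report",
    "timecourse_report",
    "design_summary_report",
]

RUN2_FIRST_STOP_INDEX = 31  # 1-based position of the first run-2 stop trial
_STOP_QUANTILE_SIZE = 15


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        return (float("nan"), float("nan"))
    m = values.mean()
    half = stats.t.ppf(0.5 + level / 2, values.size - 1) * values.std(ddof=1) / np.sqrt(
        values.size
    )
    return (float(m - half), float(m + half))


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    p = k / n
    half = stats.norm.ppf(0.5 + level / 2) * np.sqrt(p * (1 - p) / n)
    return (float(max(p - half, 0.0)), float(min(p + half, 1.0)))


def context_independence_report(cohort: list[SubjectDataset]) -> dict:
    """Stop-failure vs go RT/accuracy and the accuracy-by-SSD curve.

    Go RT means are reported both over all overt go responses and over
    correct-choice responses only.  The violator flag per subject is mean
    stop-failure RT > mean overt go RT on recategorized outcomes.
    """
    per_subject = []
    acc_rows = []
    for ds in cohort:
        ds = recategorize_trials(ds)
        sf_rts, sf_correct = [], []
        for t in ds.stop_trials():
            if t.coded_outcome is Outcome.INCORRECT_STOP and t.first_rt is not None:
                sf_rts.append(float(t.first_rt))
                sf_correct.append(t.responses[0][1] is t.go_direction)
                acc_rows.append(
                    (t.ssd_ms, t.responses[0][1] is t.go_direction)
                )
        go_rts, go_correct = [], []
        for t in ds.go_trials():
            if t.first_rt is not None:
                go_rts.append(float(t.first_rt))
                go_correct.append(t.coded_outcome is Outcome.CORRECT_GO)
        flag = flag_context_violators(ds)
        per_subject.append(
            {
                "subject_id": ds.subject_id,
                "mean_stop_failure_rt": np.mean(sf_rts) if sf_rts else np.nan,
                "mean_go_rt_overt": np.mean(go_rts) if go_rts else np.nan,
                "mean_go_rt_correct": (
                    np.mean([r for r, c in zip(go_rts, go_correct) if c])
                    if any(go_correct)
                    else np.nan
                ),
                "acc_stop_failure": np.mean(sf_correct) if sf_correct else np.nan,
                "acc_go_overt": np.mean(go_correct) if go_correct else np.nan,
                "violator": flag.flagged,
            }
        )
    subj = pd.DataFrame(per_subject)
    diff_rt = subj["mean_go_rt_overt"] - subj["mean_stop_failure_rt"]
    diff_acc = subj["acc_go_overt"] - subj["acc_stop_failure"]
    evaluable = subj["violator"].notna()
    n_violators = int(subj.loc[evaluable, "violator"].fillna(False).sum())

    acc_df = pd.DataFrame(acc_rows, columns=["ssd", "correct"])
    curve = []
    for ssd, block in acc_df.groupby("ssd"):
        k, n = int(block["correct"].sum()), len(block)
        lo, hi = _binom_ci(k, n)
        curve.append(
            {"ssd": ssd, "n": n, "accuracy": k / n, "ci_low": lo, "ci_high": hi}
        )
    return {
        "per_subject": subj,
        "pooled": {
            "mean_stop_failure_rt": float(np.nanmean(subj["mean_stop_failure_rt"])),
            "mean_go_rt_overt": float(np.nanmean(subj["mean_go_rt_overt"])),
            "mean_go_rt_correct": float(np.nanmean(subj["mean_go_rt_correct"])),
            "rt_difference_ci": _t_ci(diff_rt.to_numpy()),
            "acc_stop_failure": float(np.nanmean(subj["acc_stop_failure"])),
            "acc_go_overt": float(np.nanmean(subj["acc_go_overt"])),
            "acc_difference_ci": _t_ci(diff_acc.to_numpy()),
        },
        "violators": {
            "count": n_violators,
            "n_evaluable": int(evaluable.sum()),
            "fraction": n_violators / max(int(evaluable.sum()), 1),
        },
        "accuracy_by_ssd": pd.DataFrame(curve),
    }


def sequence_report(cohort: list[SubjectDataset], max_lag: int = 12) -> dict:
    """Conditional stop probabilities and post-stop-signal slowing.

    ``p_stop_given_lag`` row ``k`` is P(stop at trial t | the most recent
    stop was k trials before), pooled across subjects and compared with
    the uniform-probability reference (the cohort's overall stop rate).
    Post-stop-signal slowing (RT after a stop trial minus RT before it,
    overt correct go responses only, run boundaries dropped) is averaged
    within four 15-stop-trial quantiles with 95% t-intervals across
    subjects.
    """
    lag_total = np.zeros(max_lag + 1)
    lag_stop = np.zeros(max_lag + 1)
    slowing_by_subject: list[list[list[float]]] = []
    n_stop_total = 0
    n_trials_total = 0
    for ds in cohort:
        quartile_vals: list[list[float]] = [[] for _ in range(4)]
        stop_counter = 0
        by_run: dict[int, list] = {}
        for t in ds.trials:
            by_run.setdefault(t.run, []).append(t)
        for run_trials in by_run.values():
            since = None
            for i, t in enumerate(run_trials):
                is_stop = t.trial_type is TrialType.STOP
                n_trials_total += 1
                n_stop_total += is_stop
                if since is not None and since <= max_lag:
                    lag_total[since] += 1
                    lag_stop[since] += is_stop
                if is_stop:
                    stop_counter += 1
                    if 0 < i < len(run_trials) - 1:
                        before, after = run_trials[i - 1], run_trials[i + 1]
                        if (
                            before.trial_type is TrialType.GO
                            and after.trial_type is TrialType.GO
                            and before.coded_outcome is Outcome.CORRECT_GO
                            and after.coded_outcome is Outcome.CORRECT_GO
                        ):
                            q = min((stop_counter - 1) // _STOP_QUANTILE_SIZE, 3)
                            quartile_vals[q].append(
                                float(after.first_rt) - float(before.first_rt)
                            )
                    since = 1
                elif since is not None:
                    since += 1
        slowing_by_subject.append(
            [np.mean(v) if v else np.nan for v in quartile_vals]
        )

    lag_df = pd.DataFrame(
        {
            "lag": np.arange(1, max_lag + 1),
            "n": lag_total[1:],
            "p_stop": np.divide(
                lag_stop[1:], lag_total[1:], out=np.full(max_lag, np.nan),
                where=lag_total[1:] > 0,
            ),
        }
    )
    overall_p_stop = n_stop_total / max(n_trials_total, 1)
    slow = np.asarray(slowing_by_subject, dtype=float)
    quartiles = []
    for q in range(4):
        vals = slow[:, q]
        lo, hi = _t_ci(vals)
        quartiles.append(
            {
                "quantile": q + 1,
                "mean_slowing_ms": float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else float("nan"),
                "ci_low": lo,
                "ci_high": hi,
                "n_subjects": int(np.sum(~np.isnan(vals))),
            }
        )
    return {
        "p_stop_given_lag": lag_df,
        "p_stop_overall": overall_p_stop,
        "uniform_reference": overall_p_stop,
        "post_stop_slowing": pd.DataFrame(quartiles),
    }


def timecourse_report(cohort: list[SubjectDataset]) -> dict:
    """Stop accuracy and SSD per stop-trial position (1-based, nominally 1-60).

    Datasets with differing stop-trial counts are aligned up to the
    minimum count.  The first stop trial of run 2 (position 31 in the
    standard design) is flagged as the staircase-reset boundary.
    """
    acc_rows, ssd_rows = [], []
    for ds in cohort:
        stops = ds.stop_trials()
        acc_rows.append(
            [t.coded_outcome is Outcome.CORRECT_STOP for t in stops]
        )
        ssd_rows.append([t.ssd_ms for t in stops])
    n_min = min(len(r) for r in acc_rows)
    acc = np.array([r[:n_min] for r in acc_rows], dtype=float)
    ssd = np.array([r[:n_min] for r in ssd_rows], dtype=float)
    rows = []
    for i in range(n_min):
        alo, ahi = _t_ci(acc[:, i])
        slo, shi = _t_ci(ssd[:, i])
        rows.append(
            {
                "stop_trial": i + 1,
                "stop_accuracy": float(acc[:, i].mean()),
                "acc_ci_low": alo, "acc_ci_high": ahi,
                "mean_ssd": float(ssd[:, i].mean()),
                "ssd_ci_low": slo, "ssd_ci_high": shi,
            }
        )
    return {
        "by_stop_trial": pd.DataFrame(rows),
        "run2_boundary_stop_trial": RUN2_FIRST_STOP_INDEX,
        "n_stop_trials_aligned": n_min,
    }


def design_summary_report(cohort: list[SubjectDataset]) -> dict:
    """Stimulus-duration distributions, SSD histogram and stop probability."""
    go_dur_go, go_dur_stop, ssds = [], [], []
    n_stop = n_total = 0
    for ds in cohort:
        for t in ds.trials:
            n_total += 1
            if t.trial_type is TrialType.STOP:
                n_stop += 1
                go_dur_stop.append(t.go_stim_duration_ms)
                ssds.append(t.ssd_ms)
            else:
                go_dur_go.append(t.go_stim_duration_ms)
    ssds_arr = np.asarray(ssds, dtype=float)
    vals, counts = np.unique(ssds_arr, return_counts=True)
    return {
        "go_stim_duration": {
            "go_trials": {
                "mean": float(np.mean(go_dur_go)), "sd": float(np.std(go_dur_go)),
                "n": len(go_dur_go),
            },
            "stop_trials": {
                "mean": float(np.mean(go_dur_stop)), "sd": float(np.std(go_dur_stop)),
                "n": len(go_dur_stop),
            },
        },
        "ssd_histogram": pd.DataFrame({"ssd": vals, "n": counts}),
        "frac_ssd0": float(np.mean(ssds_arr == 0)) if ssds else float("nan"),
        "frac_ssd_gt700": float(np.mean(ssds_arr > 700)) if ssds else float("nan"),
        "p_stop": n_stop / max(n_total, 1),
    }
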