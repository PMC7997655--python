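"""Synthetic ABCD-style stop-signal task engine.

Simulates the task exactly as delivered to subjects — two runs of 180
trials, 1-in-6 stop trials with no immediate stop repeats, a 1-up/1-down
SSD staircase starting at 50 ms, the go/stop stimulus-duration rules, and
the response-window bookkeeping — wired to any behavioural generating
model from :mod:`stoprace.race`.  The engine can also inject the task's
known data corruptions:

* the *faulty-SSD* glitch (a sub-50 ms response at SSD 50 propagates as a
  recorded response on every later stop trial, with SSD stuck at 0);
* outcome *miscodings* (correct stops with responses coded as correct,
  first go responses overwritten by later ones, flipped-button errors),
  which corrupt only the coded outcome and never the underlying
  responses, with ground truth retained on each trial.

Defaults reproduce the published task design and corruption prevalences;
pass ``TaskConfig.clean()`` for an uncorrupted engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import (
    GoDirection,
    Outcome,
    SubjectDataset,
    TrialRecord,
    TrialType,
)
from .race import GeneratingModel, ModelKind, RaceParams, race_go_trials, race_stop_trials

__all__ = [
    "TaskConfig",
    "generate_trial_sequence",
    "update_ssd",
    "stimulus_durations",
    "simulate_session",
    "simulate_cohort",
]


def _default_issue6_rates() -> dict[str, float]:
    # Per-source-trial flip probabilities chosen so the contamination of each
    # *coded* class matches the published prevalences (6.9% of coded
    # incorrect-go, 2.8% of coded correct-go, 0.4% of coded correct-stop) at
    # ~90% go accuracy and ~50% stop success.
    return {
        "go_correct_coded_incorrect": 0.006,
        "go_incorrect_coded_correct": 0.26,
        "stop_failure_coded_success": 0.004,
    }


@dataclass(frozen=True)
class TaskConfig:
    """Task-engine parameters (defaults emulate the ABCD design, flaws included)."""

    n_runs: int = 2
    trials_per_run: int = 180
    p_stop: float = 1.0 / 6.0
    ssd_start_ms: int = 50
    ssd_step_ms: int = 50
    ssd_min_ms: int = 0
    ssd_max_ms: int = 900
    stop_signal_ms: int = 300
    go_max_ms: int = 1000
    p_stop_after_one_gap: float = 0.018
    issue3_rate: float = 0.027
    issue6_rates: dict = field(default_factory=_default_issue6_rates)
    uniform_sequence: bool = False
    reset_ssd_each_run: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_stop", "p_stop_after_one_gap", "issue3_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability")
        for v in self.issue6_rates.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("issue6 rates must be probabilities")
        for name in ("ssd_start_ms", "ssd_min_ms", "ssd_max_ms"):
            if getattr(self, name) % self.ssd_step_ms != 0:
                raise ValueError(f"{name} must be a multiple of ssd_step_ms")
        if not self.ssd_min_ms <= self.ssd_start_ms <= self.ssd_max_ms:
            raise ValueError("need ssd_min <= ssd_start <= ssd_max")

    @classmethod
    def clean(cls, **kwargs) -> "TaskConfig":
        """Config with every data corruption disabled."""
        kwargs.setdefault("issue3_rate", 0.0)
        kwargs.setdefault(
            "issue6_rates",
            {k: 0.0 for k in _default_issue6_rates()},
        )
        return cls(**kwargs)

    @property
    def n_stop_per_run(self) -> int:
        return round(self.p_stop * self.trials_per_run)


def _uniform_composition(total: int, cells: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random composition of ``total`` into ``cells`` parts >= 0."""
    if cells == 1:
        return np.array([total])
    bars = np.sort(rng.choice(total + cells - 1, size=cells - 1, replace=False))
    padded = np.concatenate(([-1], bars, [total + cells - 1]))
    return np.diff(padded) - 1


def _one_run_sequence(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    n, n_stop = config.trials_per_run, config.n_stop_per_run
    if n_stop < 1 or n_stop > n:
        raise ValueError("infeasible stop-trial count")
    is_stop = np.zeros(n, dtype=bool)
    if config.uniform_sequence:
        is_stop[rng.choice(n, size=n_stop, replace=False)] = True
        return is_stop
    # Constrained placement: no immediate stop repeats; a stop follows a stop
    # at gap 2 (exactly one intervening go) with probability
    # p_stop_after_one_gap, gaps otherwise uniform over feasible layouts.
    n_gaps = n_stop - 1
    k = int(rng.binomial(n_gaps, config.p_stop_after_one_gap)) if n_gaps else 0
    base = k * 1 + (n_gaps - k) * 2
    leftover = (n - n_stop) - base
    if leftover < 0:
        raise ValueError(
            "infeasible sequence constraints: not enough go trials to separate stops"
        )
    gap2 = np.zeros(n_gaps, dtype=bool)
    if k:
        gap2[rng.choice(n_gaps, size=k, replace=False)] = True
    extra = _uniform_composition(leftover, (n_gaps - k) + 2, rng)
    lead = int(extra[0])
    tail_extra = iter(extra[1:-1])
    pos = lead
    is_stop[pos] = True
    for j in range(n_gaps):
        gos = 1 if gap2[j] else 2 + int(next(tail_extra))
        pos += gos + 1
        is_stop[pos] = True
    return is_stop


def generate_trial_sequence(
    config: TaskConfig, rng_seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Boolean is-stop sequence for a full session (runs concatenated).

    Exactly ``round(p_stop * trials_per_run)`` stop trials per run; no two
    adjacent stop trials (also across the run boundary); deterministic for
    a given seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    )
    runs: list[np.ndarray] = []
    for _ in range(config.n_runs):
        seq = _one_run_sequence(config, rng)
        if not config.uniform_sequence:
            while runs and runs[-1][-1] and seq[0]:
                seq = _one_run_sequence(config, rng)
        runs.append(seq)
    return np.concatenate(runs)


def update_ssd(ssd_ms: int, stop_success: bool, config: TaskConfig) -> int:
    """1-up/1-down staircase step: +step after a success, -step after a failure."""
    if not config.ssd_min_ms <= ssd_ms <= config.ssd_max_ms:
        raise ValueError(f"ssd {ssd_ms} out of bounds")
    step = config.ssd_step_ms if stop_success else -config.ssd_step_ms
    return int(np.clip(ssd_ms + step, config.ssd_min_ms, config.ssd_max_ms))


def stimulus_durations(
    trial_type: TrialType,
    ssd_ms: int | None,
    first_rt_ms: int | None,
    config: TaskConfig | None = None,
) -> tuple[int, int | None]:
    """(go stimulus duration, stop stimulus duration) for one trial.

    Go trials: the go stimulus stays up for 1000 ms or the response,
    whichever comes first.  Stop trials: the go stimulus is replaced by
    the stop signal after SSD (or removed at the response); the stop
    signal lasts 300 ms, or 1000-SSD when SSD exceeds 700 ms.
    """
    config = config or TaskConfig()
    if trial_type is TrialType.GO:
        go_dur = config.go_max_ms if first_rt_ms is None else min(first_rt_ms, config.go_max_ms)
        return int(go_dur), None
    if ssd_ms is None:
        raise ValueError("stop trial requires an SSD")
    go_dur = ssd_ms if first_rt_ms is None else min(first_rt_ms, ssd_ms)
    stop_dur = (
        config.stop_signal_ms if ssd_ms <= 700 else config.go_max_ms - ssd_ms
    )
    return int(go_dur), int(stop_dur)


def _period_rts(
    trial_type: TrialType, rt: int | None, ssd: int | None, stop_dur: int | None
) -> tuple[int, int, int]:
    """ABCD-style per-period latencies; 0 encodes "no response in period"."""
    if rt is None:
        return (0, 0, 0)
    if trial_type is TrialType.GO:
        return (rt, 0, 0)
    if rt <= ssd:
        return (rt, 0, 0)
    if rt <= ssd + stop_dur:
        return (0, rt, 0)
    return (0, 0, rt)


def _go_outcome(responded: bool, correct: bool) -> Outcome:
    if not responded:
        return Outcome.GO_OMISSION
    return Outcome.CORRECT_GO if correct else Outcome.INCORRECT_GO


def _inject_issue6(
    trials: list[TrialRecord], rates: dict, rng: np.random.Generator
) -> list[TrialRecord]:
    out = []
    for t in trials:
        coded = t.coded_outcome
        if coded is Outcome.CORRECT_GO and rng.random() < rates.get(
            "go_correct_coded_incorrect", 0.0
        ):
            coded = Outcome.INCORRECT_GO
        elif coded is Outcome.INCORRECT_GO and rng.random() < rates.get(
            "go_incorrect_coded_correct", 0.0
        ):
            coded = Outcome.CORRECT_GO
        elif coded is Outcome.INCORRECT_STOP and rng.random() < rates.get(
            "stop_failure_coded_success", 0.0
        ):
            coded = Outcome.CORRECT_STOP
        out.append(replace(t, coded_outcome=coded) if coded is not t.coded_outcome else t)
    return out


def simulate_session(
    model: GeneratingModel,
    config: TaskConfig | None = None,
    rng_seed: int | np.random.Generator | None = None,
    subject_id: str = "sim",
) -> SubjectDataset:
    """One subject's full session under a generating model.

    The staircase evolves from the model's stop-trial outcomes; the
    faulty-SSD glitch fires (when drawn at ``issue3_rate``) at the first
    stop trial whose SSD equals the 50 ms start; miscodings are injected
    per ``issue6_rates`` with ground truth kept in ``truth_outcome``.
    Deterministic given the seed.
    """
    config = config or TaskConfig()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    )
    is_stop = generate_trial_sequence(config, rng)

    glitchy = bool(rng.random() < config.issue3_rate)
    glitch_latency = int(rng.integers(1, config.ssd_start_ms)) if glitchy else None
    glitch_choice = GoDirection.LEFT if rng.random() < 0.5 else GoDirection.RIGHT
    triggered = False

    trials: list[TrialRecord] = []
    ssd = config.ssd_start_ms
    i = 0
    for run in range(1, config.n_runs + 1):
        if config.reset_ssd_each_run and not triggered:
            ssd = config.ssd_start_ms
        for idx in range(config.trials_per_run):
            direction = GoDirection.LEFT if rng.random() < 0.5 else GoDirection.RIGHT
            if not is_stop[i]:
                rt_f, correct, omission = race_go_trials(model.race, rng, 1)
                rt = None if omission[0] else int(round(float(rt_f[0])))
                choice = direction if correct[0] else direction.opposite
                responses = () if rt is None else ((rt, choice),)
                outcome = _go_outcome(rt is not None, bool(correct[0]))
                go_dur, _ = stimulus_durations(TrialType.GO, None, rt, config)
                trials.append(
                    TrialRecord(
                        subject_id=subject_id, run=run, trial_index=idx,
                        trial_type=TrialType.GO, go_direction=direction,
                        ssd_ms=None,
                        period_rts=_period_rts(TrialType.GO, rt, None, None),
                        responses=responses, coded_outcome=outcome,
                        go_stim_duration_ms=go_dur, stop_stim_duration_ms=None,
                        truth_outcome=outcome,
                    )
                )
            else:
                if triggered:
                    rec_ssd, rt, choice = 0, glitch_latency, glitch_choice
                    responded = True
                elif glitchy and ssd == config.ssd_start_ms:
                    # the glitch: a response faster than the 50 ms SSD is
                    # recorded and then propagated to every later stop trial
                    rec_ssd, rt, choice = ssd, glitch_latency, glitch_choice
                    responded, triggered = True, True
                else:
                    resp, rt_f, correct = race_stop_trials(
                        model.kind, float(ssd), model.race, rng,
                        mixture=model.mixture, size=1,
                    )
                    responded = bool(resp[0])
                    rt = int(round(float(rt_f[0]))) if responded else None
                    choice = (
                        (direction if correct[0] else direction.opposite)
                        if responded
                        else direction
                    )
                    rec_ssd = ssd
                outcome = Outcome.INCORRECT_STOP if responded else Outcome.CORRECT_STOP
                go_dur, stop_dur = stimulus_durations(
                    TrialType.STOP, rec_ssd, rt, config
                )
                trials.append(
                    TrialRecord(
                        subject_id=subject_id, run=run, trial_index=idx,
                        trial_type=TrialType.STOP, go_direction=direction,
                        ssd_ms=rec_ssd,
                        period_rts=_period_rts(TrialType.STOP, rt, rec_ssd, stop_dur),
                        responses=() if rt is None else ((rt, choice),),
                        coded_outcome=outcome,
                        go_stim_duration_ms=go_dur,
                        stop_stim_duration_ms=stop_dur,
                        truth_outcome=outcome,
                    )
                )
                if triggered:
                    ssd = config.ssd_min_ms
                else:
                    ssd = update_ssd(ssd, not responded, config)
            i += 1

    trials = _inject_issue6(trials, config.issue6_rates, rng)
    return SubjectDataset(
        subject_id=subject_id,
        trials=trials,
        metadata={"site": "sim", "button_flip": False, "issue3_injected": glitchy},
    )


def simulate_cohort(
    spec,
    model_kind: ModelKind | str,
    config: TaskConfig | None = None,
    rng_seed: int | np.random.Generator | None = None,
    mixture=None,
    sigma: float | None = None,
) -> list[SubjectDataset]:
    """A cohort of sessions with between-subject parameter variation.

    ``spec`` is an :class:`stoprace.experiments.CohortSpec`; per-subject
    go RT and SSRT are drawn by
    :func:`stoprace.experiments.sample_subject_params` and converted to
    drifts; the diffusion coefficient is calibrated once at the cohort
    mean go drift.  Reproducible given the seed.
    """
    from . import experiments  # deferred: experiments imports this module

    config = config or TaskConfig()
    kind = ModelKind(model_kind)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(spec.seed if rng_seed is None else rng_seed)
    )
    if sigma is None:
        sigma = experiments.calibrated_sigma(spec)
    cohort = []
    for j in range(spec.n_subjects):
        params = experiments.sample_subject_params(spec, rng)
        race = RaceParams(mu_go=params.mu_go, mu_stop=params.mu_stop, sigma=sigma)
        model = GeneratingModel(kind, race, mixture)
        cohort.append(
            simulate_session(model, config, rng, subject_id=f"sub-{j:05d}")
        )
    return cohort
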