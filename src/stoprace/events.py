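"""Trial-level event tables for ABCD-style stop-signal task data.

The on-disk format is tab-separated text, one row per task trial, with a
documented header (see :data:`COLUMNS`).  Files from other pipelines with
different column names can be read through a :class:`Dialect` that maps
canonical column names onto the file's own header.

Conventions
-----------
* Latencies are integer milliseconds.
* ``period_rts`` is the triple of recorded latencies for the three
  constituent periods of a trial (SSD period, stop-signal period,
  post-signal fixation period); ``0`` encodes "no response in this period",
  matching the ABCD output convention.  The ``responses`` list (overt
  responses as ``latency:choice`` pairs relative to trial onset) is the
  authoritative record; ``period_rts`` is carried alongside it.
* ``trial_index`` is 0-based within a run; runs are numbered from 1.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "TrialType",
    "GoDirection",
    "Outcome",
    "TrialRecord",
    "SubjectDataset",
    "Dialect",
    "COLUMNS",
    "read_events",
    "write_events",
    "validate_dataset",
    "FormatError",
]

GO_MAX_MS = 1000
SSD_STEP_MS = 50
SSD_MAX_MS = 900
STOP_SIGNAL_MS = 300
TRIALS_PER_RUN = 180
N_RUNS = 2


class FormatError(ValueError):
    """Raised when an events file cannot be interpreted."""


class TrialType(str, enum.Enum):
    GO = "go"
    STOP = "stop"


class GoDirection(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "GoDirection":
        return GoDirection.RIGHT if self is GoDirection.LEFT else GoDirection.LEFT


class Outcome(str, enum.Enum):
    CORRECT_GO = "correct_go"
    INCORRECT_GO = "incorrect_go"
    GO_OMISSION = "go_omission"
    CORRECT_STOP = "correct_stop"
    INCORRECT_STOP = "incorrect_stop"


#: Canonical column order of the on-disk format.
COLUMNS = [
    "subject_id",
    "run",
    "trial_index",
    "trial_type",
    "go_direction",
    "ssd_ms",
    "ssd_period_rt_ms",
    "signal_period_rt_ms",
    "post_period_rt_ms",
    "responses",
    "coded_outcome",
    "go_stim_duration_ms",
    "stop_stim_duration_ms",
    "truth_outcome",
    "original_outcome",
]

_REQUIRED = COLUMNS[:13]  # truth/original outcome columns are optional


@dataclass(frozen=True)
class TrialRecord:
    """One task trial.

    ``truth_outcome`` carries the generator's ground-truth outcome on
    synthetic data (absent on real files); ``original_outcome`` preserves
    the pre-recode coding after :func:`stoprace.qc.recategorize_trials`.
    """

    subject_id: str
    run: int
    trial_index: int
    trial_type: TrialType
    go_direction: GoDirection
    ssd_ms: int | None
    period_rts: tuple[int, int, int]
    responses: tuple[tuple[int, GoDirection], ...]
    coded_outcome: Outcome
    go_stim_duration_ms: int
    stop_stim_duration_ms: int | None
    truth_outcome: Outcome | None = None
    original_outcome: Outcome | None = None

    @property
    def first_response(self) -> tuple[int, GoDirection] | None:
        return self.responses[0] if self.responses else None

    @property
    def first_rt(self) -> int | None:
        return self.responses[0][0] if self.responses else None

    def violations(self) -> list[str]:
        """Contract violations of this record (empty when valid)."""
        errs: list[str] = []
        where = f"run {self.run} trial {self.trial_index}"
        if self.trial_type is TrialType.STOP:
            if self.ssd_ms is None:
                errs.append(f"{where}: stop trial without ssd_ms")
            else:
                if self.ssd_ms % SSD_STEP_MS != 0 or not 0 <= self.ssd_ms <= SSD_MAX_MS:
                    errs.append(f"{where}: ssd_ms {self.ssd_ms} outside 0..900 step 50")
                expected_stop_dur = (
                    STOP_SIGNAL_MS if self.ssd_ms <= 700 else GO_MAX_MS - self.ssd_ms
                )
                if self.stop_stim_duration_ms != expected_stop_dur:
                    errs.append(
                        f"{where}: stop_stim_duration_ms {self.stop_stim_duration_ms}"
                        f" != {expected_stop_dur}"
                    )
                expected_go_dur = (
                    min(self.first_rt, self.ssd_ms)
                    if self.first_rt is not None
                    else self.ssd_ms
                )
                if self.go_stim_duration_ms != expected_go_dur:
                    errs.append(
                        f"{where}: go_stim_duration_ms {self.go_stim_duration_ms}"
                        f" != {expected_go_dur}"
                    )
        else:
            if self.ssd_ms is not None:
                errs.append(f"{where}: go trial with ssd_ms")
            if self.stop_stim_duration_ms is not None:
                errs.append(f"{where}: go trial with stop_stim_duration_ms")
            expected_go_dur = (
                min(self.first_rt, GO_MAX_MS) if self.first_rt is not None else GO_MAX_MS
            )
            if self.go_stim_duration_ms != expected_go_dur:
                errs.append(
                    f"{where}: go_stim_duration_ms {self.go_stim_duration_ms}"
                    f" != {expected_go_dur}"
                )
        return errs


@dataclass
class SubjectDataset:
    """Ordered trials of one subject (nominally two runs of 180 trials)."""

    subject_id: str
    trials: list[TrialRecord]
    metadata: dict = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    def run_lengths(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for t in self.trials:
            counts[t.run] = counts.get(t.run, 0) + 1
        return counts

    @property
    def complete(self) -> bool:
        lengths = self.run_lengths()
        return sorted(lengths) == list(range(1, N_RUNS + 1)) and all(
            n == TRIALS_PER_RUN for n in lengths.values()
        )

    def go_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.trial_type is TrialType.GO]

    def stop_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.trial_type is TrialType.STOP]

    def with_trials(self, trials: Iterable[TrialRecord]) -> "SubjectDataset":
        return SubjectDataset(
            subject_id=self.subject_id,
            trials=list(trials),
            metadata=dict(self.metadata),
            violations=list(self.violations),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [_record_to_row(t) for t in self.trials], columns=COLUMNS
        )


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for foreign event files.

    ``aliases`` maps canonical column names (see :data:`COLUMNS`) to the
    names used in the file.  Unmapped canonical names are looked up
    verbatim.
    """

    aliases: dict[str, str] = field(default_factory=dict)
    delimiter: str = "\t"

    def resolve(self, canonical: str) -> str:
        return self.aliases.get(canonical, canonical)

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        ) or {}
        return cls(
            aliases=dict(data.get("aliases", {})),
            delimiter=data.get("delimiter", "\t"),
        )


def _serialize_responses(responses: Sequence[tuple[int, GoDirection]]) -> str:
    return ";".join(f"{lat}:{choice.value}" for lat, choice in responses)


def _parse_responses(text: str) -> tuple[tuple[int, GoDirection], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        lat, choice = item.split(":")
        out.append((int(lat), GoDirection(choice)))
    return tuple(out)


def _record_to_row(t: TrialRecord) -> dict:
    return {
        "subject_id": t.subject_id,
        "run": t.run,
        "trial_index": t.trial_index,
        "trial_type": t.trial_type.value,
        "go_direction": t.go_direction.value,
        "ssd_ms": "" if t.ssd_ms is None else t.ssd_ms,
        "ssd_period_rt_ms": t.period_rts[0],
        "signal_period_rt_ms": t.period_rts[1],
        "post_period_rt_ms": t.period_rts[2],
        "responses": _serialize_responses(t.responses),
        "coded_outcome": t.coded_outcome.value,
        "go_stim_duration_ms": t.go_stim_duration_ms,
        "stop_stim_duration_ms": "" if t.stop_stim_duration_ms is None else t.stop_stim_duration_ms,
        "truth_outcome": "" if t.truth_outcome is None else t.truth_outcome.value,
        "original_outcome": "" if t.original_outcome is None else t.original_outcome.value,
    }


def _row_to_record(row: dict) -> TrialRecord:
    def opt_int(v) -> int | None:
        return None if v in ("", None) else int(v)

    def opt_outcome(v) -> Outcome | None:
        return None if v in ("", None) else Outcome(v)

    return TrialRecord(
        subject_id=str(row["subject_id"]),
        run=int(row["run"]),
        trial_index=int(row["trial_index"]),
        trial_type=TrialType(row["trial_type"]),
        go_direction=GoDirection(row["go_direction"]),
        ssd_ms=opt_int(row["ssd_ms"]),
        period_rts=(
            int(row["ssd_period_rt_ms"]),
            int(row["signal_period_rt_ms"]),
            int(row["post_period_rt_ms"]),
        ),
        responses=_parse_responses(str(row["responses"])),
        coded_outcome=Outcome(row["coded_outcome"]),
        go_stim_duration_ms=int(row["go_stim_duration_ms"]),
        stop_stim_duration_ms=opt_int(row["stop_stim_duration_ms"]),
        truth_outcome=opt_outcome(row.get("truth_outcome", "")),
        original_outcome=opt_outcome(row.get("original_outcome", "")),
    )


def validate_dataset(dataset: SubjectDataset) -> list[str]:
    """All contract violations of a dataset.

    Record-level duration/SSD rules plus ordering ((run, trial_index)
    strictly increasing) and completeness (two runs of 180 trials).
    Violations are collected, never silently dropped.
    """
    errs: list[str] = []
    for t in dataset.trials:
        errs.extend(t.violations())
    keys = [(t.run, t.trial_index) for t in dataset.trials]
    if keys != sorted(set(keys)):
        errs.append("trial order is not strictly increasing in (run, trial_index)")
    if not dataset.complete:
        errs.append(
            "incomplete dataset: run lengths "
            f"{dataset.run_lengths()} != {{1: {TRIALS_PER_RUN}, 2: {TRIALS_PER_RUN}}}"
        )
    return errs


def read_events(path: str | Path, dialect: Dialect | None = None) -> SubjectDataset:
    """Read one subject's events table.

    Violations of the trial contracts (including incompleteness) are
    collected on ``dataset.violations``; only a missing required column is
    a hard :class:`FormatError`.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    rename = {dialect.resolve(c): c for c in COLUMNS if dialect.resolve(c) in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = ""
    trials = [_row_to_record(row) for row in df.to_dict("records")]
    subject_id = trials[0].subject_id if trials else Path(path).stem
    dataset = SubjectDataset(subject_id=subject_id, trials=trials)
    dataset.violations = validate_dataset(dataset)
    return dataset


def write_events(dataset: SubjectDataset, path: str | Path) -> Path:
    """Write a dataset as canonical TSV (bit-stable for identical input)."""
    path = Path(path)
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def recode_outcome(trial: TrialRecord, outcome: Outcome, keep_original: bool = True) -> TrialRecord:
    """Copy of ``trial`` with ``coded_outcome`` replaced (provenance kept)."""
    original = trial.original_outcome if trial.original_outcome is not None else trial.coded_outcome
    return replace(
        trial,
        coded_outcome=outcome,
        original_outcome=original if keep_original else trial.original_outcome,
    )
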