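"""Inhibition functions and SSRT estimators.

All estimators implement the *integration with replacement* method: go
omissions are replaced with the maximum RT (3000 ms), the go RTs are
sorted ascending, the n-th RT with ``n = ceil(p_respond * N)`` (1-based)
is taken, and the stop-signal delay is subtracted.  Three pairings with
SSD-determination schemes are provided:

* ``tracking`` — overall P(respond|signal) and mean SSD over all stop
  trials (the standard pairing with a 1-up/1-down staircase);
* ``fixed_by_ssd`` — one estimate per SSD of a fixed grid, using that
  SSD's P(respond) and that SSD as the delay;
* ``weighted`` — a weighted sum of per-SSD estimates with weights given
  by a subject's SSD distribution (restricted to 0-500 ms).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import Outcome, SubjectDataset

__all__ = [
    "MAX_RT_MS",
    "SSRTEstimate",
    "inhibition_function",
    "ssrt_integration",
    "ssrt_by_ssd",
    "ssrt_weighted",
    "ssrt_tracking",
    "estimate_from_dataset",
    "DegenerateStoppingError",
]

MAX_RT_MS = 3000.0
SSD_WEIGHT_MAX_MS = 500


class DegenerateStoppingError(ValueError):
    """P(respond|signal) is 0 or 1: no valid SSRT (subject-exclusion rule)."""


@dataclass(frozen=True)
class SSRTEstimate:
    """An SSRT estimate with its method provenance."""

    value: float
    method: str  # tracking_integration | fixed_by_ssd | weighted
    n_go: int
    n_stop: int
    p_respond: float
    mean_ssd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("SSRT estimate must be finite")


def inhibition_function(ssd, responded) -> pd.DataFrame:
    """P(respond|signal) per SSD with counts.

    Columns: ``ssd``, ``n_stop``, ``n_respond``, ``p_respond``; one row
    per observed SSD, ascending.
    """
    df = pd.DataFrame({"ssd": np.asarray(ssd), "responded": np.asarray(responded, bool)})
    out = (
        df.groupby("ssd")["responded"]
        .agg(n_stop="size", n_respond="sum")
        .reset_index()
        .sort_values("ssd", ignore_index=True)
    )
    out["p_respond"] = out["n_respond"] / out["n_stop"]
    return out


def _replaced_sorted_go(go_rts, max_rt: float) -> np.ndarray:
    """Go RTs with omissions (NaN/None/inf) replaced by ``max_rt``, sorted."""
    g = np.asarray(
        [max_rt if (v is None) else float(v) for v in np.ravel(go_rts)], dtype=float
    )
    g = np.where(np.isfinite(g), g, max_rt)
    return np.sort(g)


def ssrt_integration(
    go_rts,
    p_respond: float,
    mean_ssd: float,
    max_rt: float = MAX_RT_MS,
    method: str = "tracking_integration",
    n_stop: int = 0,
) -> SSRTEstimate:
    """Integration-with-replacement SSRT.

    ``go_rts`` may contain None/NaN/inf for omissions (replaced by
    ``max_rt``).  Degenerate ``p_respond`` (0 or 1) raises
    :class:`DegenerateStoppingError`, matching the subject-exclusion rule
    for degenerate stopping performance.
    """
    g = _replaced_sorted_go(go_rts, max_rt)
    if g.size == 0:
        raise ValueError("need at least one go RT")
    if not 0.0 < p_respond < 1.0:
        raise DegenerateStoppingError(f"degenerate p_respond={p_respond}")
    n = int(math.ceil(p_respond * g.size))
    value = float(g[n - 1]) - float(mean_ssd)
    return SSRTEstimate(
        value=value,
        method=method,
        n_go=int(g.size),
        n_stop=int(n_stop),
        p_respond=float(p_respond),
        mean_ssd=float(mean_ssd),
    )


def ssrt_by_ssd(
    go_rts,
    ssd,
    responded,
    ssd_max: int = SSD_WEIGHT_MAX_MS,
    max_rt: float = MAX_RT_MS,
) -> pd.DataFrame:
    """Per-SSD SSRT table over SSDs in [0, ``ssd_max``].

    Columns: ``ssd``, ``n_stop``, ``p_respond``, ``ssrt_ssd``, ``p_ssd``
    (weights over the included SSDs, renormalized after dropping SSDs
    with degenerate P(respond), which are excluded with a warning).
    """
    inhib = inhibition_function(ssd, responded)
    inhib = inhib[inhib["ssd"] <= ssd_max].copy()
    rows = []
    for rec in inhib.itertuples(index=False):
        if not 0.0 < rec.p_respond < 1.0:
            warnings.warn(
                f"SSD {rec.ssd}: degenerate p_respond={rec.p_respond}; row dropped",
                stacklevel=2,
            )
            continue
        est = ssrt_integration(
            go_rts, rec.p_respond, float(rec.ssd), max_rt=max_rt,
            method="fixed_by_ssd", n_stop=int(rec.n_stop),
        )
        rows.append(
            {"ssd": rec.ssd, "n_stop": rec.n_stop, "p_respond": rec.p_respond,
             "ssrt_ssd": est.value}
        )
    table = pd.DataFrame(rows, columns=["ssd", "n_stop", "p_respond", "ssrt_ssd"])
    if len(table):
        table["p_ssd"] = table["n_stop"] / table["n_stop"].sum()
    else:
        table["p_ssd"] = pd.Series(dtype=float)
    return table


def ssrt_weighted(table: pd.DataFrame, weights=None) -> SSRTEstimate:
    """Weighted sum of per-SSD SSRTs: sum_SSD P(SSD) * SSRT_SSD.

    ``weights`` (mapping SSD -> proportion) defaults to the table's own
    ``p_ssd`` column; externally supplied weights are restricted to the
    table's SSDs and renormalized.  Weights must sum to 1 (after
    renormalization) within numerical tolerance.
    """
    if not len(table):
        raise ValueError("empty per-SSD table")
    if weights is None:
        w = table["p_ssd"].to_numpy(dtype=float)
    else:
        w = np.array([float(weights.get(int(s), 0.0)) for s in table["ssd"]])
        if w.sum() <= 0:
            raise ValueError("weights do not overlap the table's SSDs")
        w = w / w.sum()
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1 over the included SSDs")
    value = float(np.dot(w, table["ssrt_ssd"].to_numpy(dtype=float)))
    n_stop = int(table["n_stop"].sum())
    return SSRTEstimate(
        value=value,
        method="weighted",
        n_go=0,
        n_stop=n_stop,
        p_respond=float(np.dot(w, table["p_respond"].to_numpy(dtype=float))),
        mean_ssd=float(np.dot(w, table["ssd"].to_numpy(dtype=float))),
    )


def ssrt_tracking(go_rts, ssd, responded, max_rt: float = MAX_RT_MS) -> SSRTEstimate:
    """Tracking-based SSRT: overall P(respond) and mean SSD over stop trials."""
    responded = np.asarray(responded, bool)
    ssd = np.asarray(ssd, float)
    if responded.size == 0:
        raise ValueError("need at least one stop trial")
    return ssrt_integration(
        go_rts,
        float(responded.mean()),
        float(ssd.mean()),
        max_rt=max_rt,
        method="tracking_integration",
        n_stop=int(responded.size),
    )


def _dataset_arrays(dataset: SubjectDataset):
    """(go RTs incl. omissions as NaN, stop SSDs, stop responded) from coded outcomes."""
    go_rts = [
        float(t.first_rt) if t.first_rt is not None else np.nan
        for t in dataset.go_trials()
    ]
    stops = dataset.stop_trials()
    ssd = np.array([t.ssd_ms for t in stops], dtype=float)
    responded = np.array(
        [t.coded_outcome is Outcome.INCORRECT_STOP for t in stops], dtype=bool
    )
    return np.asarray(go_rts, dtype=float), ssd, responded


def estimate_from_dataset(
    dataset: SubjectDataset, method: str = "tracking"
) -> SSRTEstimate | pd.DataFrame:
    """SSRT from an events dataset (recategorize first for trustworthy coding).

    ``method`` is ``tracking``, ``by-ssd`` (returns the per-SSD table) or
    ``weighted`` (weights = the subject's own SSD distribution).
    """
    go_rts, ssd, responded = _dataset_arrays(dataset)
    if method == "tracking":
        return ssrt_tracking(go_rts, ssd, responded)
    if method == "by-ssd":
        return ssrt_by_ssd(go_rts, ssd, responded)
    if method == "weighted":
        return ssrt_weighted(ssrt_by_ssd(go_rts, ssd, responded))
    raise ValueError(f"unknown method {method!r}")
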