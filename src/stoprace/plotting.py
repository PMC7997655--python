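"""Matplotlib figures for the standard diagnostic views."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_inhibition_function", "plot_accuracy_by_ssd", "plot_ssd_histogram"]


def plot_inhibition_function(curves: dict[str, pd.DataFrame], ax=None):
    """P(respond|signal) by SSD, one line per labelled curve.

    ``curves`` maps a label to an :func:`stoprace.ssrt.inhibition_function`
    frame (columns ``ssd``, ``p_respond``).
    """
    if ax is None:
        _, ax = plt.subplots()
    for label, df in curves.items():
        ax.plot(df["ssd"], df["p_respond"], marker="o", label=label)
    ax.set_xlabel("SSD (ms)")
    ax.set_ylabel("P(respond | stop signal)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_accuracy_by_ssd(curve: pd.DataFrame, ax=None):
    """Choice accuracy on stop-failure trials across SSD with 95% CI band."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["ssd"], curve["accuracy"], marker="o")
    if {"ci_low", "ci_high"} <= set(curve.columns):
        ax.fill_between(curve["ssd"], curve["ci_low"], curve["ci_high"], alpha=0.3)
    ax.axhline(0.5, ls="--", color="grey", lw=1)
    ax.set_xlabel("SSD (ms)")
    ax.set_ylabel("stop-failure choice accuracy")
    ax.set_ylim(0, 1)
    return ax


def plot_ssd_histogram(hist: pd.DataFrame, ax=None):
    """Stop-signal delay histogram (columns ``ssd``, ``n``)."""
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(hist["ssd"], hist["n"], width=40)
    ax.set_xlabel("SSD (ms)")
    ax.set_ylabel("stop trials")
    return ax
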