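"""Minimal plotting helpers for the exported experiment tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def reliability_diagram(curve: pd.DataFrame, ax=None, label: str | None = None):
    """Calibration curve from :func:`logituq.evaluation.calibration_curve`."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], color="grey", lw=1, ls="--")
    ax.plot(
        curve["mean_probability"], curve["empirical_frequency"], marker="o", label=label
    )
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("empirical frequency")
    if label:
        ax.legend()
    return ax


def stratification_curve(strat_frame: pd.DataFrame, ax=None, label: str | None = None):
    """NLL over uncertainty-ranked sliding windows."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(strat_frame["window_rank"], strat_frame["mean_nll"], label=label)
    ax.set_xlabel("uncertainty rank (window)")
    ax.set_ylabel("mean NLL")
    if label:
        ax.legend()
    return ax


def uncertainty_scatter(
    table: pd.DataFrame, x: str, ax=None, label: str | None = None, n_max: int = 2000
):
    """Epistemic uncertainty against a toy-table column (probability,
    density, or label_noise)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sub = table.iloc[: n_max]
    ax.scatter(sub[x], sub["u_epi"], s=4, alpha=0.4, label=label)
    ax.set_xlabel(x)
    ax.set_ylabel("epistemic uncertainty")
    if label:
        ax.legend()
    return ax
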