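"""Thin matplotlib layer over the plot-ready aggregates.

The tested surface is :func:`~sgtools.describe.average_gain_profile`
and :func:`~sgtools.describe.trajectory_data`; these helpers only draw.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .describe import average_gain_profile, trajectory_data
from .identify import WideDataset

__all__ = ["plot_sg", "plot_sg_trajectories"]


def plot_sg(
    bysg: pd.DataFrame,
    measure_name: Optional[str] = None,
    tx_start_var: Optional[str] = None,
    tx_end_var: Optional[str] = None,
    group_column: Optional[str] = None,
    ylab: str = "score",
    ax=None,
):
    """Average around-gain profile with an SD ribbon; optional group overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if group_column is None:
        groups = [(None, bysg)]
    else:
        groups = list(bysg.groupby(group_column))
    for label, sub in groups:
        prof = average_gain_profile(sub, measure_name, tx_start_var, tx_end_var)
        x = range(len(prof))
        ax.plot(x, prof["mean"], marker="o", label=None if label is None else str(label))
        lo = prof["mean"] - prof["sd"].fillna(0)
        hi = prof["mean"] + prof["sd"].fillna(0)
        ax.fill_between(x, lo, hi, alpha=0.2)
        ax.set_xticks(list(x))
        ax.set_xticklabels(prof["position"])
    ax.set_xlabel("session relative to gain")
    ax.set_ylabel(ylab)
    if group_column is not None:
        ax.legend(title=group_column)
    return ax


def plot_sg_trajectories(
    data: WideDataset,
    subject_ids: Optional[Sequence] = None,
    predicate: Optional[Callable] = None,
    ylab: str = "score",
    ax=None,
):
    """Spaghetti plot of individual subjects' session-by-session scores."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    long = trajectory_data(data, subject_ids, predicate)
    for sid, sub in long.groupby("id", sort=False):
        ax.plot(sub["session"], sub["value"], marker="o", alpha=0.7, label=str(sid))
    ax.set_xlabel("session")
    ax.set_ylabel(ylab)
    if long["id"].nunique() <= 12:
        ax.legend(title="id", fontsize="small")
    return ax
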