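"""Plots of the two headline relationships.

Matplotlib figures for the rank-versus-speak/listen-ratio association
and the lnAA-versus-rank association; both take the tidy frames the
pipeline writes and return the Axes for further styling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_rank_vs_ratios(fig_data: pd.DataFrame, ax=None):
    """Scatter of speaking/listening TBV and pulse ratios against status
    rank (1 = high), with least-squares trend lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for col, marker, label in (
        ("tbv_speak_listen_ratio", "o", "TBV speak/listen"),
        ("bpm_speak_listen_ratio", "s", "Pulse speak/listen"),
    ):
        sub = fig_data.dropna(subset=[col])
        ax.scatter(sub["final_rank"], sub[col], marker=marker, alpha=0.6,
                   label=label)
        if sub.shape[0] >= 2 and sub["final_rank"].nunique() > 1:
            b, a = np.polyfit(sub["final_rank"], sub[col], 1)
            xs = np.linspace(sub["final_rank"].min(), sub["final_rank"].max(), 2)
            ax.plot(xs, a + b * xs)
    ax.axhline(1.0, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("status rank (1 = high)")
    ax.set_ylabel("speak/listen ratio")
    ax.legend()
    return ax


def plot_lnaa_vs_rank(fig_data: pd.DataFrame, ax=None):
    """lnAA mean level against status rank, one trend line per study."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for study, sub in fig_data.groupby("study"):
        ax.scatter(sub["final_rank"], sub["lnAA_mean"], alpha=0.6,
                   label=f"study {study}")
        if sub.shape[0] >= 2 and sub["final_rank"].nunique() > 1:
            b, a = np.polyfit(sub["final_rank"], sub["lnAA_mean"], 1)
            xs = np.linspace(sub["final_rank"].min(), sub["final_rank"].max(), 2)
            ax.plot(xs, a + b * xs)
    ax.set_xlabel("status rank (1 = high)")
    ax.set_ylabel("mean lnAA")
    ax.legend()
    return ax
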