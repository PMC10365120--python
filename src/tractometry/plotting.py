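"""Profile figures: group mean +/- SE curves with significance asterisks."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .profiles import METRICS

_GROUP_COLORS = ("tab:blue", "tab:red")


def plot_group_profiles(profiles: pd.DataFrame, results, tract: str,
                        hemisphere: str,
                        metrics: tuple[str, ...] = ("fa", "ad", "rd"),
                        save_path: str | None = None):
    """One panel per metric: group mean curve, +/- SE dashed envelopes, and
    an asterisk over every FWE-significant node.

    ``results`` is a :class:`~tractometry.stats.GroupComparisonResults` (or
    any mapping ``(tract, hemisphere, metric) -> GroupStatsResult``).
    """
    sub = profiles[(profiles["tract"] == tract)
                   & (profiles["hemisphere"] == hemisphere)]
    groups = list(pd.unique(sub["group"]))
    fig, axes = plt.subplots(1, len(metrics), figsize=(4.2 * len(metrics), 3.2),
                             squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        for group, color in zip(groups, _GROUP_COLORS):
            g = sub[sub["group"] == group]
            stats_ = g.groupby("node")[metric].agg(["mean", "sem"])
            nodes = stats_.index.to_numpy()
            ax.plot(nodes, stats_["mean"], color=color, label=group)
            ax.plot(nodes, stats_["mean"] + stats_["sem"], "--", color=color,
                    lw=0.8)
            ax.plot(nodes, stats_["mean"] - stats_["sem"], "--", color=color,
                    lw=0.8)
        try:
            res = results[(tract, hemisphere, metric)]
        except (KeyError, TypeError):
            res = None
        if res is not None and res.significant.any():
            sig_nodes = np.flatnonzero(res.significant) + 1
            y = sub.groupby("node")[metric].mean().max()
            ax.plot(sig_nodes, np.full(len(sig_nodes), y * 1.05), "k*",
                    ms=5, label="p < %.2g (FWE)" % res.alpha)
        ax.set_xlabel("node")
        ax.set_ylabel(metric.upper())
        ax.set_title(f"{hemisphere} {tract}")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if save_path:
        fig.savefig(save_path, dpi=110)
        plt.close(fig)
    return fig
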