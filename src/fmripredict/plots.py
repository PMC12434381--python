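"""Plots mirroring the standard outputs: per-feature score distributions,
scaling heatmaps, and scan-time tradeoff curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scaling import ScalingGrid, scan_time_axis


def plot_score_distributions(per_split: pd.DataFrame, out_path: str | Path) -> None:
    """Boxplots of per-split scores, one panel per (target, model)."""
    groups = list(per_split.groupby(["target", "model"]))
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(8, 2.5 * max(len(groups), 1)), squeeze=False
    )
    for ax, ((target, model), df) in zip(axes.ravel(), groups):
        features = (
            df.groupby("feature")["score"].mean().sort_values(ascending=False).index
        )
        data = [df.loc[df["feature"] == f, "score"].to_numpy() for f in features]
        ax.boxplot(data, tick_labels=list(features), showmeans=True)
        ax.axhline(0.0, ls=":", color="k", lw=0.8)
        ax.set_title(f"{target} — {model}")
        ax.set_ylabel("score")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_scaling_heatmap(grid: ScalingGrid, out_path: str | Path) -> None:
    """Mean score for every (train fraction, session amount) cell."""
    table = grid.mean_table()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(table.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(table.columns)), [f"{c:g}" for c in table.columns])
    ax.set_yticks(range(len(table.index)), [f"{r:g}" for r in table.index])
    ax.set_xlabel("scanning sessions")
    ax.set_ylabel("fraction of training subjects")
    ax.set_title(f"{grid.target_name} from {grid.feature_name} ({grid.model_name})")
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            ax.text(j, i, f"{table.iat[i, j]:.2f}", ha="center", va="center",
                    color="w", fontsize=8)
    fig.colorbar(im, ax=ax, label="mean score")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_scan_time_curves(grid: ScalingGrid, out_path: str | Path) -> None:
    """Score vs cumulative scan minutes, one line per training fraction.

    The band is the SD of the per-split scores at each point.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    minutes = scan_time_axis(np.asarray(grid.session_amounts))
    for frac in grid.train_fractions:
        means = np.array(
            [grid.cells[(frac, a)].mean() for a in grid.session_amounts]
        )
        sds = np.array([grid.cells[(frac, a)].std() for a in grid.session_amounts])
        ax.plot(minutes, means, marker="o", label=f"{frac:g} of training set")
        ax.fill_between(minutes, means - sds, means + sds, alpha=0.2)
    ax.set_xlabel("scan time (min)")
    ax.set_ylabel("mean score")
    ax.set_title(f"{grid.target_name} from {grid.feature_name} ({grid.model_name})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
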