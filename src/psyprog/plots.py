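"""Rendering helpers: group-effect box plots, dendrogram, metric bars."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from .clustering import ClusterResult
from .mini_items import MINI_LABELS


def plot_group_effects(maps_matrix: np.ndarray, effect_table: pd.DataFrame,
                       path: str) -> None:
    """Sorted box plot of per-item effect sizes across patients.

    Items run top-to-bottom from most negative to most positive median;
    Bonferroni-significant items are marked with an asterisk.
    """
    order = effect_table.sort_values("sort_rank")["item_id"].to_numpy()
    data = [maps_matrix[:, i - 1] for i in order]
    labels = [("* " if sig else "") + MINI_LABELS[i - 1]
              for i, sig in zip(order,
                                effect_table.sort_values("sort_rank")
                                ["significant"])]
    fig, ax = plt.subplots(figsize=(7, 12))
    ax.boxplot(data, orientation="horizontal", showfliers=False)
    ax.set_yticks(range(1, len(order) + 1), labels, fontsize=6)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("effect on P(remission)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(result: ClusterResult, path: str) -> None:
    """Dendrogram of the Ward linkage over patient importance maps."""
    fig, ax = plt.subplots(figsize=(9, 4))
    dendrogram(result.linkage_matrix, ax=ax, no_labels=True,
               color_threshold=(result.linkage_matrix[-(result.k - 1), 2]
                                if result.k > 1 else 0.0))
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_variant_comparison(comparison: pd.DataFrame, path: str) -> None:
    """Bar chart of the with/without-comorbidity metric comparison."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(comparison))
    w = 0.35
    ax.bar(x - w / 2, comparison["mean_without"], w,
           yerr=comparison["sd_without"], label="without comorbidity",
           capsize=3)
    ax.bar(x + w / 2, comparison["mean_with"], w,
           yerr=comparison["sd_with"], label="with comorbidity", capsize=3)
    for xi, stars in zip(x, comparison["stars"]):
        ax.text(xi, 1.02, stars, ha="center", fontsize=9)
    ax.set_xticks(x, comparison["metric"])
    ax.set_ylim(0, 1.1)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
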