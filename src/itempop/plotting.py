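"""Plain matplotlib exports of the two headline views.

Violin plots of the resampled frequency-weighted score distributions per
population, and box plots of the all-pairs Tregitope-adjusted iTEM
distributions annotated with the differential allele pairs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_violin(results, score_type: str = "adjusted", path: str | Path | None = None):
    """Violin plot of resampled population score distributions per protein."""
    df = results.population_scores
    df = df[df["score_type"] == score_type]
    proteins = sorted(df["protein"].unique())
    populations = sorted(df["population"].unique())
    fig, ax = plt.subplots(figsize=(1.8 * max(len(proteins), 2) + 2, 4))
    width = 0.8 / max(len(populations), 1)
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for j, pop in enumerate(populations):
        data = [
            df[(df["protein"] == p) & (df["population"] == pop)]["score"].to_numpy()
            for p in proteins
        ]
        pos = np.arange(len(proteins)) + (j - (len(populations) - 1) / 2) * width
        parts = ax.violinplot(data, positions=pos, widths=width * 0.9, showmedians=True)
        for body in parts["bodies"]:
            body.set_facecolor(colors[j % len(colors)])
            body.set_alpha(0.6)
    ax.set_xticks(np.arange(len(proteins)))
    ax.set_xticklabels(proteins, rotation=30, ha="right")
    ax.set_ylabel(f"{score_type} frequency-weighted score")
    ax.legend(populations, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_item_boxes(results, path: str | Path | None = None):
    """Box plot of adjusted iTEM scores per protein, differential pairs marked."""
    df = results.item_frame
    proteins = sorted(df["protein"].unique())
    data = [
        df[df["protein"] == p]["adjusted_item"].to_numpy() for p in proteins
    ]
    fig, ax = plt.subplots(figsize=(1.8 * max(len(proteins), 2) + 2, 4))
    ax.boxplot(data, tick_labels=proteins, whis=(0, 100))
    # mark pairs with the largest between-population joint-probability gaps
    marked = {
        (d.pair.allele_a, d.pair.allele_b): d for d in results.differentials
    }
    for i, p in enumerate(proteins):
        sub = df[df["protein"] == p]
        for _, row in sub.iterrows():
            key = (row["allele_a"], row["allele_b"])
            if key in marked:
                d = marked[key]
                ax.scatter(
                    i + 1,
                    row["adjusted_item"],
                    s=2000 * abs(d.diff),
                    alpha=0.5,
                    color="tab:blue" if d.diff < 0 else "tab:green",
                )
    ax.set_ylabel("Tregitope-adjusted iTEM score")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
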