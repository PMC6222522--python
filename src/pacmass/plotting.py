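"""Kendrick-plane figures: defect scatter and RT-vs-KNM bubble chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["kendrick_scatter", "bubble_plot", "save_figure"]


def kendrick_scatter(plot_data: pd.DataFrame, ax=None):
    """KMD (y) vs KNM (x): black dots for every database entry, red circles
    around identified formulas."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(plot_data["knm"], plot_data["kmd"], s=8, c="black", zorder=2)
    hits = plot_data[plot_data["identified"]]
    if len(hits):
        ax.scatter(
            hits["knm"], hits["kmd"], s=60, facecolors="none", edgecolors="red",
            linewidths=1.2, zorder=3, label="identified",
        )
        ax.legend(frameon=False)
    ax.set_xlabel("Kendrick nominal mass")
    ax.set_ylabel("Kendrick mass defect")
    return ax


def bubble_plot(plot_data: pd.DataFrame, *, size_scale: float = 1.0):
    """One panel per sample: retention time (y) vs KNM (x), dot area
    proportional to summed peak area."""
    samples = sorted(plot_data["sample"].unique())
    fig, axes = plt.subplots(1, max(len(samples), 1), figsize=(5 * max(len(samples), 1), 5), sharey=True)
    if len(samples) <= 1:
        axes = [axes]
    max_area = plot_data["area"].max() if len(plot_data) else 1.0
    for ax, sample in zip(axes, samples):
        sub = plot_data[plot_data["sample"] == sample]
        ax.scatter(
            sub["knm"], sub["rt"], s=size_scale * 300.0 * sub["area"] / max_area,
            alpha=0.5, edgecolors="k", linewidths=0.3,
        )
        ax.set_title(str(sample))
        ax.set_xlabel("Kendrick nominal mass")
    axes[0].set_ylabel("Retention time (min)")
    fig.tight_layout()
    return fig


def save_figure(fig_or_ax, path) -> None:
    """Write a figure as SVG or PNG (by extension)."""
    fig = fig_or_ax if hasattr(fig_or_ax, "savefig") else fig_or_ax.figure
    fig.savefig(str(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
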