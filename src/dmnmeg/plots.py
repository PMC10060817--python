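"""Report figures: band-power profiles, adjacency heatmaps, hub histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_band_power(band_power: pd.DataFrame, path: str | Path) -> None:
    """Per-ROI band-power profiles, one line per condition (12 panels)."""
    rois = list(dict.fromkeys(band_power["roi"]))
    bands = list(dict.fromkeys(band_power["band"]))
    conditions = list(dict.fromkeys(band_power["condition"]))
    fig, axes = plt.subplots(3, 4, figsize=(14, 9), sharex=True, sharey=True)
    for ax, roi in zip(axes.ravel(), rois):
        sub = band_power[band_power["roi"] == roi]
        for cond in conditions:
            means = [sub[(sub["condition"] == cond) & (sub["band"] == b)]["value"].mean() for b in bands]
            ax.plot(bands, means, marker="o", label=cond)
        ax.set_title(roi, fontsize=9)
        ax.tick_params(labelsize=7)
    axes[0, 0].legend(fontsize=7)
    fig.supylabel("relative band power")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_adjacency(matrix: np.ndarray, labels: list[str], title: str, path: str | Path) -> None:
    """Heatmap of one (possibly averaged) AEC-c adjacency matrix."""
    fig, ax = plt.subplots(figsize=(5.5, 4.8))
    im = ax.imshow(matrix, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, label="AEC-c")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_relative_node_strength(node_strength: pd.DataFrame, bands: list[str], path: str | Path) -> None:
    """Grouped bars of mean relative node strength per ROI and condition."""
    sub = node_strength[
        (node_strength["measure"] == "relative_node_strength") & (node_strength["band"].isin(bands))
    ]
    conditions = list(dict.fromkeys(sub["condition"]))
    rois = list(dict.fromkeys(sub["roi"]))
    fig, axes = plt.subplots(len(bands), 1, figsize=(12, 3.2 * len(bands)), squeeze=False)
    width = 0.8 / max(len(conditions), 1)
    x = np.arange(len(rois))
    for ax_row, band in zip(axes, bands):
        ax = ax_row[0]
        for k, cond in enumerate(conditions):
            means = [
                sub[(sub["condition"] == cond) & (sub["band"] == band) & (sub["roi"] == r)]["value"].mean()
                for r in rois
            ]
            ax.bar(x + k * width, means, width, label=cond)
        ax.set_xticks(x + width, rois, rotation=45, fontsize=8)
        ax.set_ylabel(f"{band}\nmean relative node strength", fontsize=8)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
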