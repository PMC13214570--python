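"""Box-plot and ROC figures for ROI-level group comparisons."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluate import ROCResult

__all__ = ["plot_roi_boxplots", "plot_roc_curve"]


def plot_roi_boxplots(
    summary: pd.DataFrame,
    path: str | Path,
    value_col: str = "summary_mean",
    rois: tuple[str, ...] = ("putamen", "caudate", "striatum"),
) -> None:
    """Side-by-side HC/PD box plots of ROI summaries, one panel per ROI."""
    fig, axes = plt.subplots(1, len(rois), figsize=(3 * len(rois), 3.2), sharey=True)
    for ax, roi in zip(axes if len(rois) > 1 else [axes], rois):
        sub = summary[summary["roi"] == roi]
        data = [
            sub.loc[sub["group"] == "HC", value_col],
            sub.loc[sub["group"] == "PD", value_col],
        ]
        box = ax.boxplot(data, tick_labels=["HC", "PD"], patch_artist=True)
        for patch, color in zip(box["boxes"], ("tab:blue", "tab:red")):
            patch.set_facecolor(color)
            patch.set_alpha(0.5)
        ax.set_title(roi)
    axes[0].set_ylabel("predicted binding potential")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_curve(roc: ROCResult, path: str | Path, label: str = "putamen") -> None:
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.plot(roc.fpr, roc.tpr, drawstyle="steps-post",
            label=f"{label} (AUC = {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
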