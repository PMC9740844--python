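"""Volcano and clustered-heatmap figures (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_volcano", "plot_heatmap"]

_VOLCANO_COLORS = {"increased": "tab:green", "decreased": "tab:red", "ns": "0.3"}


def plot_volcano(volcano_df: pd.DataFrame, path: str | Path, p_threshold: float = 0.05) -> None:
    """Scatter of log2 fold change vs -log10 p, colored by class."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, sub in volcano_df.groupby("volcano_class"):
        ax.scatter(sub["log2_fold_change"], sub["neg_log10_p"], s=18,
                   c=_VOLCANO_COLORS.get(cls, "0.3"), label=cls)
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.8, c="0.6")
    ax.axvline(0, ls="--", lw=0.8, c="0.6")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(clustering: dict, path: str | Path) -> None:
    """Heatmap of the clustered matrix returned by ``cluster_heatmap``."""
    mat = np.asarray(clustering["matrix"])
    fig, ax = plt.subplots(figsize=(6, max(3, 0.16 * mat.shape[0])))
    im = ax.imshow(mat, aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(clustering["metabolites"])))
    ax.set_yticklabels(clustering["metabolites"], fontsize=6)
    ax.set_xticks(range(len(clustering["samples"])))
    ax.set_xticklabels(clustering["samples"], fontsize=6, rotation=90)
    fig.colorbar(im, ax=ax, shrink=0.6, label="scaled abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
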