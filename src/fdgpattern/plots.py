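"""Optional figure output: connectivity heatmaps, ROC curves, score distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_connectivity_heatmap", "plot_roc_curve", "plot_expression_distribution"]


def plot_connectivity_heatmap(matrix: np.ndarray, title: str, path, vlim: float | None = None) -> None:
    """Symmetric diverging heatmap of a (delta-)connectivity matrix."""
    m = np.asarray(matrix, dtype=float)
    if vlim is None:
        off = ~np.eye(m.shape[0], dtype=bool)
        vlim = float(np.nanpercentile(np.abs(m[off]), 99))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m, cmap="PRGn", vmin=-vlim, vmax=vlim)
    ax.set_title(title)
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_curve(curve: pd.DataFrame, auc: float, title: str, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve["fpr"], curve["tpr"], drawstyle="steps-post", color="tab:blue")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{title}\nAUC = {auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_expression_distribution(scores: pd.DataFrame, path, value: str = "z_score") -> None:
    """Strip plot of expression z-scores per group."""
    groups = list(scores["group"].unique())
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    for i, g in enumerate(groups):
        y = scores.loc[scores["group"] == g, value]
        ax.scatter(i + rng.uniform(-0.15, 0.15, len(y)), y, s=14, alpha=0.7)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(range(len(groups)), groups, rotation=30)
    ax.set_ylabel("pattern expression (z vs HC)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
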