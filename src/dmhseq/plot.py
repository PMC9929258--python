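"""Optional scatter plot of a 2-D embedding."""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .cluster import ClusterLabels, Embedding2D


def plot_embedding(
    e: Embedding2D,
    labels: ClusterLabels | None = None,
    path: str | Path | None = None,
):
    """Scatter the t-SNE map, coloured by cluster when labels are given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    c = labels.labels if labels is not None else None
    ax.scatter(e.coords[:, 0], e.coords[:, 1], s=4, c=c, cmap="tab20",
               linewidths=0)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if labels is not None:
        for cl in range(labels.n_clusters):
            xy = e.coords[labels.labels == cl].mean(axis=0)
            ax.annotate(str(cl), xy, fontsize=8, ha="center")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
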