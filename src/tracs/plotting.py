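"""Minimal rendering of cluster networks: per-cluster GP mean with its 95%
confidence band, and the ordered path of clusters with edge labels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .datamodel import TimeSeriesMatrix
from .network import ClusterNetwork

__all__ = ["plot_network"]


def plot_network(
    network: ClusterNetwork,
    matrix: TimeSeriesMatrix | None = None,
    path: str | None = None,
):
    """One panel per cluster (in temporal order) plus a path diagram.

    Each panel shows the GP posterior mean (solid line) and the 95%
    confidence band; member profiles are drawn faintly when the matrix is
    supplied. Returns the figure.
    """
    k = len(network.order)
    fig, axes = plt.subplots(
        1, k + 1, figsize=(3.2 * (k + 1), 3.0), squeeze=False
    )
    axes = axes[0]
    node_by_id = {n.cluster: n for n in network.nodes}
    for ax, cid in zip(axes, network.order):
        node = node_by_id[cid]
        grid = np.asarray(node.grid)
        mean = np.asarray(node.mean)
        sd = np.asarray(node.sd)
        if matrix is not None:
            idx = matrix.gene_index()
            times = np.asarray(matrix.grid.points)
            for g in node.genes:
                ax.plot(times, matrix.averaged_values()[idx[g]], color="0.8", lw=0.5)
        ax.fill_between(grid, mean - 1.96 * sd, mean + 1.96 * sd, color="red", alpha=0.2)
        ax.plot(grid, mean, color="red", lw=1.5)
        ax.set_title(f"cluster {cid} ({len(node.genes)} genes)", fontsize=9)
        ax.set_xlabel("time")

    ax = axes[-1]
    ax.axis("off")
    xs = np.linspace(0.1, 0.9, k)
    for x, cid in zip(xs, network.order):
        ax.add_patch(plt.Circle((x, 0.5), 0.05, color="tab:blue", zorder=2))
        ax.text(x, 0.5, str(cid), ha="center", va="center", color="white", zorder=3)
    for (x0, x1), edge in zip(zip(xs, xs[1:]), network.edges):
        ax.annotate(
            "",
            xy=(x1 - 0.05, 0.5),
            xytext=(x0 + 0.05, 0.5),
            arrowprops=dict(arrowstyle="->", lw=1.2),
        )
        if edge.annotations:
            label = "\n".join(a.pathway_id for a in edge.annotations[:3])
            ax.text((x0 + x1) / 2, 0.58, label, ha="center", fontsize=7)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_title("cluster order", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
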