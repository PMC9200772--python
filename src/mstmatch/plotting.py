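"""Dot-plot and barcode-heatmap visualizations of matching results.

Orientation convention for match plots: columns are the query clusters,
rows are the reference clusters, with the UNASSIGNED row rendered at the
bottom; circle size and fill encode the proportion of the query cluster's
cells matched to each reference cluster.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import ClusterLabeling, GeneExpressionMatrix, MarkerGeneSet
from .matching import UNASSIGNED


def plot_cell2cluster(
    proportions: pd.DataFrame,
    path: str | None = None,
    return_value: bool = False,
    title: str = "query cells matched to reference clusters",
):
    """Dot grid of a (K+1) x L proportions table (columns sum to 1)."""
    colsums = proportions.sum(axis=0).to_numpy()
    if not np.allclose(colsums[colsums > 0], 1.0):
        raise ValueError("proportion columns must sum to 1")
    rows = [r for r in proportions.index if r != UNASSIGNED]
    if UNASSIGNED in proportions.index:
        rows.append(UNASSIGNED)  # unassigned always the bottom row
    table = proportions.loc[rows]
    n_r, n_q = table.shape
    fig, ax = plt.subplots(figsize=(1 + 0.5 * n_q, 1 + 0.4 * n_r))
    xs, ys = np.meshgrid(np.arange(n_q), np.arange(n_r))
    vals = table.to_numpy()
    sc = ax.scatter(
        xs.ravel(), ys.ravel(), s=20 + 360 * vals.ravel(), c=vals.ravel(),
        cmap="Blues", vmin=0, vmax=1, edgecolors="grey", linewidths=0.4,
    )
    ax.set_xticks(range(n_q), table.columns, rotation=90)
    ax.set_yticks(range(n_r), table.index)
    ax.invert_yaxis()
    ax.set_xlabel("query cluster")
    ax.set_ylabel("reference cluster")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="proportion of cells", shrink=0.8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
    plt.close(fig)
    return table if return_value else None


def plot_barcode(
    matrix: GeneExpressionMatrix,
    labels: ClusterLabeling,
    markers: MarkerGeneSet,
    clusters: list[str] | None = None,
    path: str | None = None,
):
    """Marker-by-cell heatmap ('cell type barcode'), cells grouped by cluster,
    genes ordered by the marker set (grouped by defining cluster when known)."""
    labels = labels.aligned_to(matrix)
    clusters = clusters or labels.clusters
    missing = [c for c in clusters if c not in labels.clusters]
    if missing:
        raise ValueError(f"requested cluster(s) absent: {missing}")
    gene_order = markers.ordered_by_group()
    gidx = matrix.gene_index()
    absent = [g for g in gene_order if g not in gidx]
    if absent:
        raise ValueError(f"marker gene(s) absent from matrix: {absent}")
    col_idx = np.concatenate([labels.indices_of(c) for c in clusters])
    img = matrix.values[np.array([gidx[g] for g in gene_order])][:, col_idx]
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.22 * len(gene_order)))
    ax.imshow(img, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_yticks(range(len(gene_order)), gene_order, fontsize=7)
    bounds = np.cumsum([len(labels.indices_of(c)) for c in clusters])
    for b in bounds[:-1]:
        ax.axvline(b - 0.5, color="white", linewidth=1)
    mids = bounds - np.diff(np.concatenate([[0], bounds])) / 2
    ax.set_xticks(mids, clusters, rotation=90, fontsize=7)
    ax.set_xlabel("cells (grouped by cluster)")
    fig.tight_layout()
    if path:
        fig.savefig(path)
    plt.close(fig)
    return fig
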