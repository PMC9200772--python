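"""Cross-platform normalization of marker expression into [0, 1] barcode patterns.

Two stages:

1. gene-wise min-max rescaling, x~_g = x_g / max(x_g), applied to every
   dataset so that dynamic ranges align across platforms;
2. optional cluster-wise weighting for high-sensitivity platforms
   (SMART-seq-like): within each cluster b the rescaled submatrix X~_b is
   multiplied row-wise by the weight vector w_b of within-cluster row means
   (or medians), then the whole submatrix is rescaled by its global maximum
   so the dynamic range tops out at 1 again.

With near-binary marker genes the weights are themselves near-binary, so the
weighting zeroes out background noise (genes expressed in a minority of
cells get median 0) while leaving on-target signal intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ClusterLabeling, FormatError, GeneExpressionMatrix

NORM_BY = ("mean", "median", "none")


@dataclass
class NormalizationConfig:
    """norm_by selects the cluster weight statistic ('none' disables weighting);
    apply_weighting_to lists the platform tags that receive weighting."""

    norm_by: str = "median"
    apply_weighting_to: tuple[str, ...] = ("smartseq",)

    def __post_init__(self) -> None:
        if self.norm_by not in NORM_BY:
            raise ValueError(f"norm_by must be one of {NORM_BY}, got {self.norm_by!r}")
        self.apply_weighting_to = tuple(self.apply_weighting_to)


def minmax_rescale(matrix: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Divide each gene row by its maximum over all cells (0/0 defined as 0)."""
    if np.any(matrix.values < 0):
        raise FormatError("min-max rescaling expects non-negative values")
    mx = matrix.values.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mx > 0, matrix.values / np.where(mx > 0, mx, 1.0), 0.0)
    return matrix.with_values(out, layer="normalized")


def weight_by_cluster_summary(
    matrix: GeneExpressionMatrix, labels: ClusterLabeling, norm_by: str = "median"
) -> GeneExpressionMatrix:
    """Apply cluster-wise summary weighting to an already-rescaled matrix.

    For each cluster b: X_b^normalized = w_b * X~_b with w_b the row means or
    medians of X~_b, then X_b^final = X_b^normalized / max(X_b^normalized).
    Cells keep their original column positions.
    """
    if norm_by not in ("mean", "median"):
        raise ValueError(f"norm_by must be 'mean' or 'median', got {norm_by!r}")
    if matrix.layer != "normalized":
        raise FormatError(
            "weighting expects a min-max rescaled matrix (layer='normalized'); "
            f"got layer={matrix.layer!r}"
        )
    labels = labels.aligned_to(matrix)
    out = np.empty_like(matrix.values)
    summarize = np.mean if norm_by == "mean" else np.median
    for cluster in labels.clusters:
        idx = labels.indices_of(cluster)
        sub = matrix.values[:, idx]
        w = summarize(sub, axis=1)
        weighted = sub * w[:, None]
        mx = weighted.max()
        if mx > 0:
            weighted = weighted / mx
        else:
            warnings.warn(
                f"cluster {cluster!r}: weighted submatrix entirely zero; left as zeros",
                stacklevel=2,
            )
        out[:, idx] = weighted
    return matrix.with_values(out, layer="normalized")


def normalize_pair(
    query: GeneExpressionMatrix,
    reference: GeneExpressionMatrix,
    q_labels: ClusterLabeling,
    r_labels: ClusterLabeling,
    config: NormalizationConfig | None = None,
) -> tuple[GeneExpressionMatrix, GeneExpressionMatrix]:
    """Min-max rescale both sides; weight only platform-tagged sides.

    Both matrices must already live in the same marker feature space (equal
    gene lists in the same order).
    """
    config = config or NormalizationConfig()
    if query.gene_ids != reference.gene_ids:
        raise FormatError("query and reference are not in the same marker feature space")
    out = []
    for matrix, labels in ((query, q_labels), (reference, r_labels)):
        rescaled = minmax_rescale(matrix)
        if config.norm_by != "none" and matrix.platform in config.apply_weighting_to:
            rescaled = weight_by_cluster_summary(rescaled, labels, config.norm_by)
        out.append(rescaled)
    return out[0], out[1]
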