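"""Core in-memory containers for expression data, cluster labels and marker sets.

The package-wide orientation convention is genes x cells (rows are genes),
matching how marker "barcode" matrices are drawn.  Estimator classes that
follow the scikit-learn convention (cells x features) transpose at their
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("counts", "logCPM", "normalized")
PLATFORMS = ("smartseq", "tenx", "spatial", "other")


class FormatError(ValueError):
    """Malformed input: duplicate identifiers, bad orientation, bad values."""


class ConsistencyError(ValueError):
    """Cross-file mismatch between expression matrices and label tables."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise FormatError(f"duplicate {what}: {dups[:10]}")
    return ids


@dataclass
class GeneExpressionMatrix:
    """A genes x cells expression matrix with a processing-layer tag.

    Parameters
    ----------
    gene_ids : ordered unique gene symbols (rows).
    cell_ids : ordered unique cell identifiers (columns).
    values : float array of shape ``(n_genes, n_cells)``.
    layer : one of ``counts`` (non-negative raw counts), ``logCPM``
        (log2(1 + CPM) by default) or ``normalized`` (values in [0, 1]).
    platform : assay platform tag; drives platform-conditional weighting.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    layer: str = "counts"
    platform: str = "other"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.platform not in PLATFORMS:
            raise FormatError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.layer in ("counts", "normalized") and np.any(self.values < 0):
            raise FormatError(f"layer={self.layer!r} requires non-negative values")
        if self.layer == "normalized" and np.any(self.values > 1 + 1e-12):
            raise FormatError("layer='normalized' requires values in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, idx: np.ndarray | list[int]) -> "GeneExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            cell_ids=[self.cell_ids[i] for i in idx],
            values=self.values[:, idx],
        )

    def with_values(self, values: np.ndarray, layer: str | None = None) -> "GeneExpressionMatrix":
        return replace(self, values=values, layer=layer or self.layer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ClusterLabeling:
    """Cell -> cluster-name map for a query or reference dataset."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "label-file cell ids")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != len(self.cell_ids):
            raise FormatError("labels and cell_ids must have equal length")

    @property
    def cluster_of(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))

    @property
    def clusters(self) -> list[str]:
        """Cluster names in first-appearance order."""
        return list(dict.fromkeys(self.labels))

    @property
    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def indices_of(self, cluster: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == cluster)

    def aligned_to(self, matrix: GeneExpressionMatrix) -> "ClusterLabeling":
        """Reorder to the matrix cell order; error on any set mismatch."""
        lookup = self.cluster_of
        missing = [c for c in matrix.cell_ids if c not in lookup]
        if missing:
            raise ConsistencyError(
                f"cells present in expression but absent from labels: {missing[:10]}"
            )
        extra = sorted(set(self.cell_ids) - set(matrix.cell_ids))
        if extra:
            raise ConsistencyError(
                f"cells present in labels but absent from expression: {extra[:10]}"
            )
        return ClusterLabeling(
            cell_ids=list(matrix.cell_ids),
            labels=[lookup[c] for c in matrix.cell_ids],
        )

    def subset(self, keep: Sequence[str]) -> tuple["ClusterLabeling", np.ndarray]:
        """Restrict to clusters in ``keep``; returns (labeling, kept cell indices)."""
        keep_set = set(keep)
        idx = np.array([i for i, lab in enumerate(self.labels) if lab in keep_set], dtype=int)
        return (
            ClusterLabeling(
                [self.cell_ids[i] for i in idx], [self.labels[i] for i in idx]
            ),
            idx,
        )


@dataclass
class MarkerGeneSet:
    """Ordered marker genes, optionally grouped by the cluster they define."""

    markers: list[str]
    group_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.markers = _check_unique(self.markers, "marker genes")
        if len(self.markers) < 2:
            raise FormatError("a marker set needs at least 2 genes")
        if self.group_of is not None:
            self.group_of = {str(k): str(v) for k, v in dict(self.group_of).items()}

    def __len__(self) -> int:
        return len(self.markers)

    def ordered_by_group(self, group_order: Sequence[str] | None = None) -> list[str]:
        """Markers grouped by defining cluster (stable within groups)."""
        if not self.group_of:
            return list(self.markers)
        groups = self.group_of
        if group_order is None:
            group_order = list(dict.fromkeys(groups.get(m, "") for m in self.markers))
        rank = {g: i for i, g in enumerate(group_order)}
        return sorted(
            self.markers,
            key=lambda m: (rank.get(groups.get(m, ""), len(rank)), self.markers.index(m)),
        )
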