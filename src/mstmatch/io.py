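"""Readers and writers for expression matrices, cluster labels and marker lists.

On-disk formats are deliberately plain: dense CSV/TSV (header row = cell ids,
first column = gene ids), MatrixMarket ``.mtx`` with ``genes.txt`` /
``barcodes.txt`` sidecars, two-column label CSV and a one-symbol-per-line
marker list with an optional second column naming the defining cluster.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ClusterLabeling, ConsistencyError, FormatError, GeneExpressionMatrix, MarkerGeneSet

_SEP = {"csv": ",", "tsv": "\t"}


def read_labels(labels_path: str | os.PathLike) -> ClusterLabeling:
    """Read a two-column (cell_id, cluster) table; the header row is optional."""
    df = pd.read_csv(labels_path, header=None, dtype=str, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"label file {labels_path} must have 2 columns (cell_id, cluster)")
    first = [str(x).strip().lower() for x in df.iloc[0, :2]]
    if first == ["cell_id", "cluster"]:
        df = df.iloc[1:]
    return ClusterLabeling(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def _read_dense(expr_path, sep: str, cells_as_rows: bool) -> GeneExpressionMatrix:
    df = pd.read_csv(expr_path, sep=sep, index_col=0, float_precision="round_trip")
    if cells_as_rows:
        df = df.T
    return GeneExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        cell_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
    )


def _read_mtx(expr_path) -> GeneExpressionMatrix:
    expr_path = Path(expr_path)
    genes_path = expr_path.with_name("genes.txt")
    cells_path = expr_path.with_name("barcodes.txt")
    for p in (genes_path, cells_path):
        if not p.exists():
            raise FormatError(f"MTX sidecar file missing: {p}")
    mat = scipy.io.mmread(expr_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = [ln.strip() for ln in genes_path.read_text().splitlines() if ln.strip()]
    cells = [ln.strip() for ln in cells_path.read_text().splitlines() if ln.strip()]
    return GeneExpressionMatrix(gene_ids=genes, cell_ids=cells, values=np.asarray(mat, float))


def read_expression(
    expr_path: str | os.PathLike,
    labels_path: str | os.PathLike,
    format: str = "csv",
    cells_as_rows: bool = False,
    platform: str = "other",
    layer: str = "counts",
) -> tuple[GeneExpressionMatrix, ClusterLabeling]:
    """Read an expression matrix plus its cluster labels, consistently ordered.

    Every cell in the expression matrix must appear in the label table and
    vice versa; mismatches raise :class:`ConsistencyError` naming the
    offending cells.
    """
    if format in _SEP:
        matrix = _read_dense(expr_path, _SEP[format], cells_as_rows)
    elif format == "mtx":
        matrix = _read_mtx(expr_path)
    else:
        raise FormatError(f"unknown format {format!r}; expected csv, tsv or mtx")
    matrix.layer = layer
    matrix.platform = platform
    matrix.__post_init__()  # re-validate with the requested tags
    labels = read_labels(labels_path).aligned_to(matrix)
    return matrix, labels


def write_expression(
    matrix: GeneExpressionMatrix, expr_path: str | os.PathLike, format: str = "csv"
) -> None:
    if format in _SEP:
        matrix.to_frame().to_csv(expr_path, sep=_SEP[format], float_format="%.17g")
    elif format == "mtx":
        expr_path = Path(expr_path)
        scipy.io.mmwrite(str(expr_path), scipy.sparse.coo_matrix(matrix.values))
        expr_path.with_name("genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        expr_path.with_name("barcodes.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        raise FormatError(f"unknown format {format!r}")


def write_labels(labels: ClusterLabeling, path: str | os.PathLike) -> None:
    pd.DataFrame({"cell_id": labels.cell_ids, "cluster": labels.labels}).to_csv(
        path, index=False
    )


def read_markers(path: str | os.PathLike) -> MarkerGeneSet:
    """One gene symbol per line; optional second column = defining cluster."""
    markers: list[str] = []
    groups: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        parts = ln.replace(",", "\t").split()
        if not parts:
            continue
        markers.append(parts[0])
        if len(parts) > 1:
            groups[parts[0]] = parts[1]
    return MarkerGeneSet(markers, group_of=groups or None)


def write_markers(markers: MarkerGeneSet, path: str | os.PathLike) -> None:
    lines = []
    for m in markers.markers:
        grp = (markers.group_of or {}).get(m)
        lines.append(f"{m}\t{grp}" if grp else m)
    Path(path).write_text("\n".join(lines) + "\n")
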