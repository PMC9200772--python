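"""Counts -> log2(CPM) preprocessing and projection into a marker feature space."""

from __future__ import annotations

import warnings

import numpy as np

from .data import FormatError, GeneExpressionMatrix, MarkerGeneSet


def cpm_log2(matrix: GeneExpressionMatrix, pseudocount: float = 1.0) -> GeneExpressionMatrix:
    """Library-size normalize to counts-per-million and log2-transform.

    value(g, c) = log2(pseudocount + 1e6 * count(g, c) / total(c)).

    The default pseudocount of 1 keeps zeros at exactly 0 and every value
    finite.  With ``pseudocount=0`` the transform is applied to nonzero
    entries only (zero counts stay 0), which reproduces a plain log2(CPM)
    on the expressed entries but is not depth-invariant at the low end.
    """
    if matrix.layer != "counts":
        raise FormatError(f"cpm_log2 expects layer='counts', got {matrix.layer!r}")
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        names = [matrix.cell_ids[i] for i in zero[:10]]
        raise FormatError(f"cells with zero total count: {names}")
    cpm = matrix.values * (1e6 / totals)
    if pseudocount > 0:
        out = np.log2(pseudocount + cpm)
    else:
        out = np.zeros_like(cpm)
        nz = cpm > 0
        out[nz] = np.log2(cpm[nz])
    return matrix.with_values(out, layer="logCPM")


def project_to_markers(
    matrix: GeneExpressionMatrix,
    markers: MarkerGeneSet,
    missing_policy: str = "zero_fill",
) -> GeneExpressionMatrix:
    """Restrict and reorder the matrix rows to the marker genes.

    The output row order is exactly the marker order.  Markers absent from
    the matrix are an error under ``missing_policy='error'``; under
    ``'zero_fill'`` they become all-zero rows with a warning (cross-platform
    probe panels routinely lack genes).
    """
    if missing_policy not in ("error", "zero_fill"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    index = matrix.gene_index()
    absent = [m for m in markers.markers if m not in index]
    if len(absent) == len(markers.markers):
        raise FormatError("no marker gene is present in the expression matrix")
    if absent and missing_policy == "error":
        raise FormatError(f"marker genes absent from matrix: {absent}")
    if absent:
        warnings.warn(
            f"{len(absent)} marker gene(s) absent from matrix, zero-filled: {absent}",
            stacklevel=2,
        )
    values = np.zeros((len(markers.markers), matrix.n_cells))
    for i, m in enumerate(markers.markers):
        if m in index:
            values[i] = matrix.values[index[m]]
    return GeneExpressionMatrix(
        gene_ids=list(markers.markers),
        cell_ids=list(matrix.cell_ids),
        values=values,
        layer=matrix.layer,
        platform=matrix.platform,
    )
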