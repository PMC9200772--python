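"""Cell-to-cluster and cluster-to-cluster matching of query data to a reference.

Both schemes repeatedly subsample ``subsamp_size`` cells from a query cluster
and a reference cluster and run the Friedman-Rafsky test in the shared marker
feature space, ``subsamp_iter`` times per cluster pair:

* cell-to-cluster: each drawn query cell's entry p_ck is max-updated with the
  iteration p-value, yielding a C x K matrix (C query cells, K reference
  clusters) in which a cell keeps the best evidence of membership seen across
  the subsets it appeared in;
* cluster-to-cluster: the pair's entry is the median p-value over iterations,
  an L x K matrix (L query clusters).

The raw matrix is BH-adjusted, and each row is assigned to the reference
cluster with the maximum adjusted p-value — or to UNASSIGNED when even the
maximum falls below ``sig_level``, the novel-cell-type signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import ClusterLabeling, FormatError, GeneExpressionMatrix, MarkerGeneSet
from ._core import iterate_pair, pair_rng

UNASSIGNED = "unassigned"


@dataclass
class MatchParams:
    """Knobs of the iterative matching schemes.

    subsamp_iter : subsampling iterations per cluster pair (default 2000).
    subsamp_size : cells drawn from each side per iteration (default 10).
    sig_level : adjusted-p threshold below which a row is UNASSIGNED (0.1).
    p_adj_method : 'BH' (Benjamini-Hochberg) or 'none'.
    metric : 'euclidean' or 'cosine' for the underlying test.
    bh_scope : 'global' adjusts over the whole flattened matrix, 'row'
        adjusts each row separately.
    target_draws : if set, subsamp_iter is raised (never lowered) per query
        cluster so each cell is expected to be drawn at least this often.
    """

    subsamp_iter: int = 2000
    subsamp_size: int = 10
    sig_level: float = 0.1
    p_adj_method: str = "BH"
    metric: str = "euclidean"
    seed: int = 0
    n_workers: int = 1
    bh_scope: str = "global"
    target_draws: int | None = None

    def __post_init__(self) -> None:
        if self.subsamp_iter < 1:
            raise ValueError("subsamp_iter must be >= 1")
        if self.subsamp_size < 3:
            raise ValueError("subsamp_size must be >= 3")
        if not 0 < self.sig_level < 1:
            raise ValueError("sig_level must be in (0, 1)")
        if self.p_adj_method not in ("BH", "none"):
            raise ValueError("p_adj_method must be 'BH' or 'none'")
        if self.bh_scope not in ("global", "row"):
            raise ValueError("bh_scope must be 'global' or 'row'")


@dataclass
class PValueMatrix:
    """Matching p-values: rows are query cells or clusters, columns are
    reference clusters.  NA marks cells never drawn against a reference
    cluster (cell2cluster only); ``coverage`` counts the draws behind each
    entry."""

    values: pd.DataFrame
    scheme: str
    adjusted: bool = False
    coverage: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in ("cell2cluster", "cluster2cluster"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def _checked_inputs(query, reference, q_labels, r_labels, params):
    if query.n_genes == 0 or query.gene_ids != reference.gene_ids:
        raise FormatError("query and reference must share a non-empty marker feature space")
    q_labels = q_labels.aligned_to(query)
    r_labels = r_labels.aligned_to(reference)
    usable_q, usable_r = [], []
    for labels, out, side in ((q_labels, usable_q, "query"), (r_labels, usable_r, "reference")):
        for cl, sz in labels.cluster_sizes.items():
            if sz < 3:
                warnings.warn(
                    f"{side} cluster {cl!r} has {sz} < 3 cells; skipped", stacklevel=3
                )
            else:
                out.append(cl)
    if not usable_q or not usable_r:
        raise FormatError("no usable clusters (need >= 3 cells per cluster)")
    return q_labels, r_labels, usable_q, usable_r


def _pair_tasks(query, reference, q_labels, r_labels, usable_q, usable_r, params):
    """One task per (query cluster j, reference cluster k) pair."""
    qv, rv = query.values.T, reference.values.T  # cells x features
    tasks = []
    for j, qc in enumerate(usable_q):
        qi = q_labels.indices_of(qc)
        n_iter = params.subsamp_iter
        if params.target_draws is not None:
            need = math.ceil(params.target_draws * len(qi) / params.subsamp_size)
            n_iter = max(n_iter, need)
        for k, rc in enumerate(usable_r):
            ri = r_labels.indices_of(rc)
            size = min(params.subsamp_size, len(qi), len(ri))
            if size < params.subsamp_size:
                warnings.warn(
                    f"pair ({qc!r}, {rc!r}): draw size reduced to {size}",
                    stacklevel=3,
                )
            tasks.append((j, k, qc, rc, qi, ri, size, n_iter, qv, rv))
    return tasks


def _run_pair(j, k, qc, rc, qi, ri, size, n_iter, qv, rv, metric, seed):
    rng = pair_rng(seed, j, k)
    pvals, drawn = iterate_pair(qv[qi], rv[ri], size, n_iter, metric, rng)
    return j, k, qi, pvals, drawn


def _run_tasks(tasks, params):
    if params.n_workers == 1 or len(tasks) == 1:
        return [_run_pair(*t, params.metric, params.seed) for t in tasks]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=params.n_workers)(
        delayed(_run_pair)(*t, params.metric, params.seed) for t in tasks
    )


def match_cell_to_cluster(
    query: GeneExpressionMatrix,
    reference: GeneExpressionMatrix,
    q_labels: ClusterLabeling,
    r_labels: ClusterLabeling,
    params: MatchParams | None = None,
) -> PValueMatrix:
    """Raw C x K matrix of max-updated per-cell matching p-values.

    Cells never drawn against some reference cluster carry NA there, with
    the draw count recorded in ``coverage``.
    """
    params = params or MatchParams()
    q_labels, r_labels, usable_q, usable_r = _checked_inputs(
        query, reference, q_labels, r_labels, params
    )
    C = query.n_cells
    K = len(usable_r)
    best = np.full((C, K), -1.0)
    cover = np.zeros((C, K), dtype=int)
    tasks = _pair_tasks(query, reference, q_labels, r_labels, usable_q, usable_r, params)
    for j, k, qi, pvals, drawn in _run_tasks(tasks, params):
        cells = qi[drawn]  # (n_iter, size) global cell indices
        np.maximum.at(best[:, k], cells.ravel(), np.repeat(pvals, drawn.shape[1]))
        np.add.at(cover[:, k], cells.ravel(), 1)
    values = np.where(cover > 0, best, np.nan)
    df = pd.DataFrame(values, index=query.cell_ids, columns=usable_r)
    covdf = pd.DataFrame(cover, index=query.cell_ids, columns=usable_r)
    meta = {"params": params, "query_clusters": usable_q}
    return PValueMatrix(df, scheme="cell2cluster", coverage=covdf, meta=meta)


def match_cluster_to_cluster(
    query: GeneExpressionMatrix,
    reference: GeneExpressionMatrix,
    q_labels: ClusterLabeling,
    r_labels: ClusterLabeling,
    params: MatchParams | None = None,
) -> PValueMatrix:
    """Raw L x K matrix of median-over-iterations matching p-values."""
    params = params or MatchParams()
    q_labels, r_labels, usable_q, usable_r = _checked_inputs(
        query, reference, q_labels, r_labels, params
    )
    tasks = _pair_tasks(query, reference, q_labels, r_labels, usable_q, usable_r, params)
    values = np.full((len(usable_q), len(usable_r)), np.nan)
    for j, k, qi, pvals, drawn in _run_tasks(tasks, params):
        values[j, k] = np.median(pvals)
    df = pd.DataFrame(values, index=usable_q, columns=usable_r)
    return PValueMatrix(df, scheme="cluster2cluster", meta={"params": params})


def adjust_pvalues(matrix: PValueMatrix, method: str = "BH") -> PValueMatrix:
    """Benjamini-Hochberg step-up over the non-NA entries (jointly by default,
    per row when the matrix was built with ``bh_scope='row'``)."""
    if matrix.adjusted:
        raise ValueError("matrix is already adjusted")
    if method not in ("BH", "none"):
        raise ValueError("method must be 'BH' or 'none'")
    vals = matrix.values.to_numpy(dtype=float).copy()
    scope = getattr(matrix.meta.get("params"), "bh_scope", "global")
    if method == "BH":
        if scope == "row":
            for i in range(vals.shape[0]):
                vals[i] = _bh_vector(vals[i])
        else:
            flat = vals.ravel()
            vals = _bh_vector(flat).reshape(vals.shape)
    out = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    meta = dict(matrix.meta, p_adj_method=method, bh_scope=scope,
                raw_values=matrix.values)
    return replace(matrix, values=out, adjusted=True, meta=meta)


def _bh_vector(p: np.ndarray) -> np.ndarray:
    out = p.copy()
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def assign_matches(adjusted: PValueMatrix, sig_level: float = 0.1) -> pd.DataFrame:
    """Per-row match call: argmax reference cluster, or UNASSIGNED.

    Exact argmax ties on the adjusted scale are resolved by the raw
    p-values when available (BH step-up flattens the top of the p
    distribution into plateaus, but is monotone in the raw p, so the raw
    ordering is the one the adjustment collapsed); a residual exact tie
    goes to the first reference column in order and is flagged.
    """
    vals = adjusted.values.to_numpy(dtype=float)
    raw = adjusted.meta.get("raw_values")
    raw = raw.to_numpy(dtype=float) if raw is not None else None
    cols = list(adjusted.values.columns)
    rows = []
    for i, unit in enumerate(adjusted.values.index):
        row = vals[i]
        if not np.isfinite(row).any():
            rows.append((unit, UNASSIGNED, np.nan, False))
            continue
        best = np.nanmax(row)
        hits = np.flatnonzero(np.isfinite(row) & (row == best))
        if len(hits) > 1 and raw is not None:
            hits = hits[raw[i, hits] == raw[i, hits].max()]
        tie = len(hits) > 1
        if best < sig_level:
            rows.append((unit, UNASSIGNED, best, tie))
        else:
            rows.append((unit, cols[hits[0]], best, tie))
    df = pd.DataFrame(rows, columns=["unit", "matched", "confidence", "tie"])
    df.attrs["reference_clusters"] = cols
    df.attrs["scheme"] = adjusted.scheme
    return df


def cell2cluster_proportions(
    assignments: pd.DataFrame,
    q_labels: ClusterLabeling,
    reference_clusters: list[str] | None = None,
) -> pd.DataFrame:
    """(K+1) x L table: fraction of each query cluster's cells matched to
    each reference cluster, with an UNASSIGNED bottom row; columns sum to 1."""
    if reference_clusters is None:
        reference_clusters = assignments.attrs.get("reference_clusters")
    if reference_clusters is None:
        reference_clusters = sorted(set(assignments["matched"]) - {UNASSIGNED})
    cluster_of = q_labels.cluster_of
    q_clusters = q_labels.clusters
    rows = list(reference_clusters) + [UNASSIGNED]
    table = pd.DataFrame(0.0, index=rows, columns=q_clusters)
    counts = pd.DataFrame(0, index=rows, columns=q_clusters)
    for unit, matched in zip(assignments["unit"], assignments["matched"]):
        counts.loc[matched, cluster_of[str(unit)]] += 1
    totals = counts.sum(axis=0)
    for col in q_clusters:
        if totals[col] > 0:
            table[col] = counts[col] / totals[col]
    return table


def two_way_match(
    p_qr: PValueMatrix, p_rq: PValueMatrix, sig_level: float = 0.1
) -> set[tuple[str, str]]:
    """Cluster pairs (l, k) with adjusted p >= sig_level in both directions."""
    for m in (p_qr, p_rq):
        if m.scheme != "cluster2cluster" or not m.adjusted:
            raise ValueError("two_way_match needs adjusted cluster2cluster matrices")
    if set(p_qr.values.index) != set(p_rq.values.columns) or set(
        p_qr.values.columns
    ) != set(p_rq.values.index):
        raise FormatError("the two matrices are not on transposed label sets")
    out = set()
    for l in p_qr.values.index:
        for k in p_qr.values.columns:
            fwd = p_qr.values.loc[l, k]
            rev = p_rq.values.loc[k, l]
            if np.isfinite(fwd) and np.isfinite(rev) and fwd >= sig_level and rev >= sig_level:
                out.add((str(l), str(k)))
    return out
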