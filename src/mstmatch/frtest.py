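"""The Friedman-Rafsky multivariate runs test on a minimum spanning tree.

Given two multivariate samples, pool the points, build the MST of the pooled
pairwise distances, and count runs: maximal same-sample subtrees left after
deleting every edge that joins the two samples.  R = (# cross-sample edges) + 1.
Few runs means the samples segregate in the tree, i.e. the distributions
differ.  Under the permutation null (labels exchangeable given the tree) the
runs count has closed-form moments

    E[R]   = 2mn/N + 1
    Var[R] = [2mn / (N(N-1))] * { (2mn - N)/N
             + [(C - N + 2) / ((N-2)(N-3))] * [N(N-1) - 4mn + 2] }

where N = m + n and C is the number of MST edge pairs sharing a node,
C = sum_v deg(v)*(deg(v)-1)/2.  The standardized statistic
W = (R - E[R]) / sqrt(Var[R]) is asymptotically standard normal, giving the
one-sided p-value p = Phi(W); the exact permutation p-value is available as
an alternative (and is the validation oracle for the normal approximation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import ndtr

METRICS = ("euclidean", "cosine")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a metric tag."""

    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class FRTestResult:
    m: int
    n: int
    runs: int
    cross_edges: int
    e_runs: float
    var_runs: float
    w_stat: float
    p_value: float | None = None
    metric: str = "euclidean"
    p_method: str = "normal"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "m", "n", "runs", "cross_edges", "e_runs", "var_runs",
            "w_stat", "p_value", "metric", "p_method")}


def compute_distances(points: np.ndarray, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between the rows of ``points`` (N x p).

    Cosine distance is 1 - sum(x*y) / (|x| |y|), which is invariant to
    positive rescaling of either vector; a zero vector has undefined angle
    and its distance to any other point is defined as 1 (neutral) with a
    warning, never NaN.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("points must be an (N >= 2) x p array")
    if metric == "euclidean":
        d = cdist(points, points, metric="euclidean")
    elif metric == "cosine":
        norms = np.linalg.norm(points, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero vector(s) under cosine metric; "
                "distance to them defined as 1",
                stacklevel=2,
            )
        safe = np.where(zero, 1.0, norms)
        unit = points / safe[:, None]
        sim = unit @ unit.T
        d = 1.0 - np.clip(sim, -1.0, 1.0)
        if zero.any():
            d[zero, :] = 1.0
            d[:, zero] = 1.0
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, 2.0)
    else:
        raise ValueError(f"metric must be one of {METRICS}")
    return DistanceMatrix(d, metric=metric)


def build_mst(dist: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Minimum spanning tree of a dense distance matrix: (N-1) x 2 edge array.

    Prim's algorithm starting from node 0; ties are broken toward the
    smallest node index (argmin-first-occurrence), so the tree is
    deterministic even with duplicate points.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    best = d[0].copy()
    parent = np.zeros(n, dtype=int)
    visited = np.zeros(n, dtype=bool)
    visited[0] = True
    best[0] = np.inf
    edges = np.empty((n - 1, 2), dtype=int)
    for k in range(n - 1):
        j = int(np.argmin(best))
        edges[k, 0], edges[k, 1] = parent[j], j
        visited[j] = True
        best[j] = np.inf
        improve = ~visited & (d[j] < best)
        best[improve] = d[j][improve]
        parent[improve] = j
    return edges


def _edge_pair_count(edges: np.ndarray, n_nodes: int) -> int:
    """C = number of MST edge pairs sharing a node = sum_v C(deg_v, 2)."""
    deg = np.bincount(edges.ravel(), minlength=n_nodes)
    return int((deg * (deg - 1) // 2).sum())


def runs_statistic(
    edges: np.ndarray, labels: np.ndarray, metric: str = "euclidean"
) -> FRTestResult:
    """Runs count and its permutation-null moments on a labelled tree.

    ``labels`` is a length-N vector with exactly two distinct values marking
    the two samples.  The p-value is not filled in; see :func:`fr_pvalue`
    and :func:`permutation_pvalue`.
    """
    edges = np.asarray(edges, dtype=int)
    labels = np.asarray(labels)
    n_total = labels.shape[0]
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 sample labels, got {uniq.size}")
    if n_total < 6:
        raise ValueError("need m + n >= 6 for stable null moments")
    m, n = int(counts[0]), int(counts[1])
    cross = int((labels[edges[:, 0]] != labels[edges[:, 1]]).sum())
    runs = cross + 1
    e_runs, var_runs = runs_moments(m, n, _edge_pair_count(edges, n_total))
    if var_runs > 0:
        w = (runs - e_runs) / np.sqrt(var_runs)
    else:
        w = np.nan
    return FRTestResult(
        m=m, n=n, runs=runs, cross_edges=cross,
        e_runs=e_runs, var_runs=var_runs, w_stat=float(w), metric=metric,
    )


def runs_moments(m: int, n: int, edge_pairs: int) -> tuple[float, float]:
    """Closed-form permutation-null mean and variance of the runs count."""
    N = m + n
    mn2 = 2.0 * m * n
    e_runs = mn2 / N + 1.0
    var_runs = (mn2 / (N * (N - 1.0))) * (
        (mn2 - N) / N
        + ((edge_pairs - N + 2.0) / ((N - 2.0) * (N - 3.0))) * (N * (N - 1.0) - 2.0 * mn2 + 2.0)
    )
    return e_runs, float(var_runs)


def fr_pvalue(result: FRTestResult) -> FRTestResult:
    """One-sided normal-approximation p-value, p = Phi(W).

    Few runs (W << 0) gives a small p: evidence the distributions differ.
    """
    if not np.isfinite(result.w_stat):
        raise ValueError(
            "variance of the runs count is not positive; use permutation_pvalue"
        )
    result.p_value = float(ndtr(result.w_stat))
    result.p_method = "normal"
    return result


def permutation_pvalue(
    edges: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FRTestResult:
    """Exact-null p-value by permuting the sample labels on the fixed tree.

    p = (1 + #{permuted R <= observed R}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    result = runs_statistic(edges, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    perm = np.tile(labels, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    cross = (perm[:, edges[:, 0]] != perm[:, edges[:, 1]]).sum(axis=1)
    runs_perm = cross + 1
    result.p_value = float((1 + (runs_perm <= result.runs).sum()) / (1 + n_perm))
    result.p_method = "permutation"
    return result


def fr_test(
    x: np.ndarray,
    y: np.ndarray,
    metric: str = "euclidean",
    p_method: str = "normal",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FRTestResult:
    """Full two-sample test: pool rows of x and y, build MST, compute p."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    pooled = np.vstack([x, y])
    labels = np.repeat([0, 1], [x.shape[0], y.shape[0]])
    edges = build_mst(compute_distances(pooled, metric=metric))
    if p_method == "permutation":
        result = permutation_pvalue(edges, labels, n_perm=n_perm, seed=seed)
    else:
        result = fr_pvalue(runs_statistic(edges, labels, metric=metric))
    result.metric = metric
    return result
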