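"""Inner loop of the subsampled pairwise matching schemes.

Work is partitioned by (query cluster, reference cluster) pair.  Each pair
gets its own RNG derived deterministically from (seed, j, k), so results do
not depend on worker count or scheduling.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .frtest import build_mst, compute_distances, runs_moments


def pair_rng(seed: int, j: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j, k)))


def iterate_pair(
    q_points: np.ndarray,
    r_points: np.ndarray,
    size: int,
    n_iter: int,
    metric: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``n_iter`` subsampled Friedman-Rafsky tests for one cluster pair.

    Each iteration draws ``size`` cells without replacement from each side
    (cells x features arrays), tests the two subsamples, and records the
    one-sided normal-approximation p-value.

    Returns
    -------
    pvals : (n_iter,) p-value per iteration.
    drawn : (n_iter, size) int, indices into ``q_points`` rows of the query
        cells selected at each iteration.
    """
    nq, nr = q_points.shape[0], r_points.shape[0]
    labels = np.repeat([0, 1], [size, size])
    pooled = np.empty((2 * size, q_points.shape[1]))
    runs = np.empty(n_iter)
    edge_pairs = np.empty(n_iter)
    drawn = np.empty((n_iter, size), dtype=int)
    for i in range(n_iter):
        qi = rng.choice(nq, size=size, replace=False)
        ri = rng.choice(nr, size=size, replace=False)
        drawn[i] = qi
        pooled[:size] = q_points[qi]
        pooled[size:] = r_points[ri]
        edges = build_mst(compute_distances(pooled, metric=metric))
        cross = int((labels[edges[:, 0]] != labels[edges[:, 1]]).sum())
        runs[i] = cross + 1
        deg = np.bincount(edges.ravel(), minlength=2 * size)
        edge_pairs[i] = (deg * (deg - 1) // 2).sum()
    e_runs, _ = runs_moments(size, size, 0)  # mean does not depend on edge_pairs
    var = np.array([runs_moments(size, size, int(c))[1] for c in edge_pairs])
    var = np.maximum(var, 1e-300)
    w = (runs - e_runs) / np.sqrt(var)
    return ndtr(w), drawn
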