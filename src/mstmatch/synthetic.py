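"""Synthetic data generators and evaluation harnesses.

Two families:

* multivariate-normal two-sample draws (default dimension p = 40) under a
  null and under location / shape / combined alternatives, used to calibrate
  the Friedman-Rafsky test and to compare the euclidean and cosine metrics
  by ROC/AUC;
* marker-structured multi-cluster count atlases with platform-style
  distortions (bimodal SMART-seq-like vs right-skewed 10X-like marginals),
  used to exercise the full matching pipeline end to end, including
  novel-cluster (leave-one-reference-cluster-out) and under-partitioning
  scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import ClusterLabeling, GeneExpressionMatrix, MarkerGeneSet
from .frtest import fr_test
from .matching import (
    MatchParams,
    UNASSIGNED,
    adjust_pvalues,
    assign_matches,
    match_cell_to_cluster,
)
from .normalize import NormalizationConfig, normalize_pair
from .preprocess import cpm_log2, project_to_markers

KINDS = ("null", "location", "shape", "both")


@dataclass
class SimulationScenario:
    """One MVN two-sample design.

    X ~ MVN_p(mu * 1, Sigma), Y ~ MVN_p(mu * 1 + delta * s, sigma_scale * Sigma)
    with Sigma the equicorrelation matrix (1 - rho) I + rho J and s the shift
    direction: the all-ones vector (``shift_pattern='uniform'``) or ones on
    the first half of the coordinates (``'half'``, a marker-pattern-style
    difference that changes the direction of the mean, not just its size).
    ``scale_y`` multiplies sample Y by a positive constant after drawing,
    emulating a cross-platform dynamic-range mismatch; combined with a
    positive baseline ``mu`` this mimics non-negative expression data whose
    two platforms differ in scale.
    """

    kind: str = "null"
    p: int = 40
    m: int = 20
    n: int = 20
    delta: float = 0.0
    sigma_scale: float = 1.0
    rho: float = 0.2
    mu: float = 0.0
    shift_pattern: str = "uniform"
    scale_y: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.kind == "null" and (self.delta != 0 or self.sigma_scale != 1):
            raise ValueError("kind='null' requires delta=0 and sigma_scale=1")
        if self.kind == "location" and self.delta == 0:
            raise ValueError("kind='location' requires delta != 0")
        if self.kind == "shape" and self.sigma_scale == 1:
            raise ValueError("kind='shape' requires sigma_scale != 1")
        if self.scale_y <= 0:
            raise ValueError("scale_y must be positive")
        if self.shift_pattern not in ("uniform", "half"):
            raise ValueError("shift_pattern must be 'uniform' or 'half'")


def _equicorr_chol(p: int, rho: float) -> np.ndarray:
    sigma = np.full((p, p), rho)
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"covariance not positive definite (rho={rho})") from e


def simulate_mvn_two_sample(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X: m x p, Y: n x p) under the scenario; reproducible by seed."""
    rng = rng or np.random.default_rng(scenario.seed)
    chol = _equicorr_chol(scenario.p, scenario.rho)
    x = rng.standard_normal((scenario.m, scenario.p)) @ chol.T + scenario.mu
    y = rng.standard_normal((scenario.n, scenario.p)) @ chol.T + scenario.mu
    if scenario.kind in ("shape", "both"):
        y = (y - scenario.mu) * np.sqrt(scenario.sigma_scale) + scenario.mu
    if scenario.kind in ("location", "both"):
        shift = np.full(scenario.p, scenario.delta)
        if scenario.shift_pattern == "half":
            shift[scenario.p // 2:] = 0.0
        y = y + shift
    return x, scenario.scale_y * y


def auc_from_pvalues(null_p: np.ndarray, alt_p: np.ndarray) -> float:
    """Area under the ROC of 'reject when p <= t': the probability that a
    random alternative p-value falls below a random null one (ties half)."""
    null_p = np.asarray(null_p, float)
    alt_p = np.asarray(alt_p, float)
    u = stats.mannwhitneyu(null_p, alt_p, alternative="two-sided").statistic
    return float(u / (null_p.size * alt_p.size))


def run_power_study(
    scenarios: list[SimulationScenario],
    metrics: tuple[str, ...] = ("euclidean", "cosine"),
    n_reps: int = 500,
    alpha_grid: tuple[float, ...] = (0.01, 0.05, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """ROC/AUC comparison of metrics across simulation scenarios.

    For each scenario and metric, draws ``n_reps`` paired replicates: one
    two-sample draw under the matched null (same marginal design, no
    difference, same scale mismatch applied to both sides) and one under the
    scenario, tests both, and summarizes the two p-value samples by AUC and
    rejection rates on ``alpha_grid``.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rows = []
    for s_idx, scen in enumerate(scenarios):
        null_scen = replace(
            scen, kind="null", delta=0.0, sigma_scale=1.0, scale_y=1.0
        )
        for metric in metrics:
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(s_idx, metrics.index(metric)))
            )
            null_p = np.empty(n_reps)
            alt_p = np.empty(n_reps)
            for r in range(n_reps):
                xn, yn = simulate_mvn_two_sample(null_scen, rng)
                # the scale mismatch is a nuisance present under H0 too
                null_p[r] = fr_test(xn, scen.scale_y * yn, metric=metric).p_value
                xa, ya = simulate_mvn_two_sample(scen, rng)
                alt_p[r] = fr_test(xa, ya, metric=metric).p_value
            row = {
                "kind": scen.kind, "metric": metric, "m": scen.m, "n": scen.n,
                "p": scen.p, "delta": scen.delta, "sigma_scale": scen.sigma_scale,
                "scale_y": scen.scale_y,
                "auc": auc_from_pvalues(null_p, alt_p),
            }
            for a in alpha_grid:
                row[f"power@{a}"] = float(np.mean(alt_p <= a))
                row[f"size@{a}"] = float(np.mean(null_p <= a))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SyntheticAtlas:
    """A marker-structured multi-cluster count atlas.

    Each cluster owns a disjoint block of ``markers_per_cluster`` genes that
    are "on" (negative-binomial with mean ``on_mean``, subject to dropout)
    in its own cells and "off" (mean ``off_mean``) elsewhere; ``noise_genes``
    are expressed everywhere at a moderate level so library sizes are stable.
    ``platform_style`` shifts the marginals: 'bimodal' emulates a
    high-sensitivity plate protocol (stronger signal, more background,
    little dropout), 'rightskew' a droplet protocol (sparser, zero-inflated).
    """

    clusters: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5")
    markers_per_cluster: int = 2
    noise_genes: int = 10
    cells_per_cluster: int = 200
    on_mean: float = 60.0
    off_mean: float = 0.05
    dropout: float = 0.1
    nb_shape: float = 2.0
    platform_style: str = "rightskew"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clusters) < 2:
            raise ValueError("need at least 2 clusters")
        if self.platform_style not in ("bimodal", "rightskew"):
            raise ValueError("platform_style must be 'bimodal' or 'rightskew'")

    @property
    def marker_set(self) -> MarkerGeneSet:
        markers, groups = [], {}
        for c in self.clusters:
            for i in range(self.markers_per_cluster):
                g = f"{c}_mk{i}"
                markers.append(g)
                groups[g] = c
        return MarkerGeneSet(markers, group_of=groups)


def _nb_counts(rng, mean, shape, size):
    """Negative binomial via gamma-Poisson; mean ``mean``, dispersion 1/shape."""
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def sample_atlas(
    atlas: SyntheticAtlas,
    rng: np.random.Generator | None = None,
    cell_prefix: str = "cell",
    label_map: dict[str, str] | None = None,
    platform: str = "tenx",
) -> tuple[GeneExpressionMatrix, ClusterLabeling]:
    """One independent draw of counts from the atlas generative model."""
    rng = rng or np.random.default_rng(atlas.seed)
    style = atlas.platform_style
    on_mean = atlas.on_mean * (4.0 if style == "bimodal" else 1.0)
    off_mean = atlas.off_mean * (6.0 if style == "bimodal" else 1.0)
    dropout = 0.05 if style == "bimodal" else atlas.dropout
    markers = atlas.marker_set
    genes = list(markers.markers) + [f"noise{i}" for i in range(atlas.noise_genes)]
    n_cells = atlas.cells_per_cluster * len(atlas.clusters)
    values = np.zeros((len(genes), n_cells))
    cell_ids, labels = [], []
    col = 0
    for c in atlas.clusters:
        idx = slice(col, col + atlas.cells_per_cluster)
        for gi, g in enumerate(markers.markers):
            own = markers.group_of[g] == c
            mean = on_mean if own else off_mean
            counts = _nb_counts(rng, mean, atlas.nb_shape, atlas.cells_per_cluster)
            if own and dropout > 0:
                counts = counts * (rng.random(atlas.cells_per_cluster) >= dropout)
            values[gi, idx] = counts
        for ni in range(atlas.noise_genes):
            values[len(markers.markers) + ni, idx] = _nb_counts(
                rng, 20.0, atlas.nb_shape, atlas.cells_per_cluster
            )
        for i in range(atlas.cells_per_cluster):
            cell_ids.append(f"{cell_prefix}_{c}_{i}")
            labels.append(label_map.get(c, c) if label_map else c)
        col += atlas.cells_per_cluster
    # guarantee positive library sizes
    zero_total = values.sum(axis=0) == 0
    values[-1, zero_total] = 1
    gem = GeneExpressionMatrix(genes, cell_ids, values, layer="counts", platform=platform)
    return gem, ClusterLabeling(cell_ids, labels)


def simulate_cell_atlas_pair(
    atlas: SyntheticAtlas,
    drop_cluster: str | None = None,
    merge_clusters: tuple[str, str] | None = None,
    query_platform_style: str | None = None,
    seed: int | None = None,
) -> dict:
    """Independent query and reference draws plus markers and a truth map.

    ``drop_cluster`` removes one cluster from the *reference* (its query
    cells become expected-UNASSIGNED: the novelty scenario);
    ``merge_clusters`` gives two query clusters one shared label (the
    under-partitioning scenario).  Returns a dict with keys ``query``,
    ``q_labels``, ``reference``, ``r_labels``, ``markers``, ``truth``.
    """
    seed = atlas.seed if seed is None else seed
    for name in filter(None, [drop_cluster, *(merge_clusters or ())]):
        if name not in atlas.clusters:
            raise ValueError(f"unknown cluster {name!r}")
    rng_ref = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    rng_qry = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    reference, r_labels = sample_atlas(atlas, rng_ref, cell_prefix="ref")

    label_map = None
    if merge_clusters:
        merged = "+".join(merge_clusters)
        label_map = {c: merged for c in merge_clusters}
    q_atlas = atlas
    if query_platform_style:
        q_atlas = replace(atlas, platform_style=query_platform_style)
    q_platform = "smartseq" if q_atlas.platform_style == "bimodal" else "tenx"
    query, q_labels = sample_atlas(
        q_atlas, rng_qry, cell_prefix="qry", label_map=label_map, platform=q_platform
    )

    if drop_cluster:
        keep = [c for c in atlas.clusters if c != drop_cluster]
        r_labels, idx = r_labels.subset(keep)
        reference = reference.subset_cells(idx)

    truth = {}
    for c in atlas.clusters:
        expected = UNASSIGNED if c == drop_cluster else c
        q_name = label_map.get(c, c) if label_map else c
        truth.setdefault(q_name, set()).add(expected)
    return {
        "query": query,
        "q_labels": q_labels,
        "reference": reference,
        "r_labels": r_labels,
        "markers": atlas.marker_set,
        "truth": {k: sorted(v) for k, v in truth.items()},
    }


def run_matching_pipeline(
    query: GeneExpressionMatrix,
    reference: GeneExpressionMatrix,
    q_labels: ClusterLabeling,
    r_labels: ClusterLabeling,
    markers: MarkerGeneSet,
    params: MatchParams | None = None,
    norm_config: NormalizationConfig | None = None,
) -> pd.DataFrame:
    """counts -> log2CPM -> marker projection -> normalization -> matching
    -> BH -> per-cell assignment.  Returns the assignment frame."""
    params = params or MatchParams()
    prep = []
    for gem in (query, reference):
        if gem.layer == "counts":
            gem = cpm_log2(gem)
        prep.append(project_to_markers(gem, markers))
    qn, rn = normalize_pair(prep[0], prep[1], q_labels, r_labels, norm_config)
    raw = match_cell_to_cluster(qn, rn, q_labels, r_labels, params)
    adj = adjust_pvalues(raw, params.p_adj_method)
    return assign_matches(adj, params.sig_level)


def binary_unassigned_scores(truth_pos: np.ndarray, pred_pos: np.ndarray) -> dict:
    """Confusion-table scores for the UNASSIGNED call as a binary classifier.

    ``truth_pos`` marks cells whose true counterpart is absent from the
    reference; ``pred_pos`` marks cells called UNASSIGNED.
    """
    truth_pos = np.asarray(truth_pos, bool)
    pred_pos = np.asarray(pred_pos, bool)
    tp = int((truth_pos & pred_pos).sum())
    tn = int((~truth_pos & ~pred_pos).sum())
    fp = int((~truth_pos & pred_pos).sum())
    fn = int((truth_pos & ~pred_pos).sum())
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / truth_pos.size,
        "type1_error": fp / (fp + tn) if fp + tn else 0.0,
    }


def loocv_unassigned_eval(
    atlas: SyntheticAtlas,
    params: MatchParams | None = None,
    norm_config: NormalizationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Leave-one-reference-cluster-out novelty evaluation.

    For each reference cluster r, matching is rerun without r; query cells
    whose true counterpart is r are the observed positives, UNASSIGNED calls
    the predicted positives.  Scores each left-out cluster as a binary
    classification: accuracy = (TP+TN)/total, type1_error = FP/(FP+TN).
    """
    params = params or MatchParams()
    rows = []
    for left_out in atlas.clusters:
        sim = simulate_cell_atlas_pair(atlas, drop_cluster=left_out, seed=seed)
        calls = run_matching_pipeline(
            sim["query"], sim["reference"], sim["q_labels"], sim["r_labels"],
            sim["markers"], params, norm_config,
        )
        cluster_of = sim["q_labels"].cluster_of
        truth_pos = np.array(
            [cluster_of[str(u)] == left_out for u in calls["unit"]]
        )
        pred_pos = (calls["matched"] == UNASSIGNED).to_numpy()
        rows.append({"left_out": left_out, **binary_unassigned_scores(truth_pos, pred_pos)})
    return pd.DataFrame(rows)
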