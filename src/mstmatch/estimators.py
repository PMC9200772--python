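"""Scikit-learn style estimators: the primary user-facing API.

These follow the sklearn conventions (``fit`` on the reference,
``predict``/``transform`` on the query, ``get_params``/``set_params``,
fitted attributes with a trailing underscore) so they compose with sklearn
pipelines and model selection.  One deliberate signature extension: the
matching schemes are defined per *query cluster*, so ``predict`` accepts
``query_labels``; when omitted, all query cells are treated as one cluster.

Arrays are cells x features (sklearn orientation); features are the marker
genes, already normalized to [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import ClusterLabeling, GeneExpressionMatrix
from .matching import (
    MatchParams,
    PValueMatrix,
    UNASSIGNED,
    adjust_pvalues,
    assign_matches,
    match_cell_to_cluster,
    match_cluster_to_cluster,
)
from .normalize import NormalizationConfig, minmax_rescale, weight_by_cluster_summary


def _as_gem(X: np.ndarray, ids_prefix: str, layer: str = "normalized") -> GeneExpressionMatrix:
    X = check_array(X, dtype=float)
    return GeneExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(X.shape[1])],
        cell_ids=[f"{ids_prefix}{i}" for i in range(X.shape[0])],
        values=X.T,
        layer=layer,
    )


def _as_labeling(y, prefix: str, n: int) -> ClusterLabeling:
    if y is None:
        y = ["all"] * n
    return ClusterLabeling([f"{prefix}{i}" for i in range(n)], [str(v) for v in y])


class _BaseMatcher(BaseEstimator):
    def __init__(
        self,
        subsamp_iter: int = 2000,
        subsamp_size: int = 10,
        sig_level: float = 0.1,
        p_adj_method: str = "BH",
        metric: str = "euclidean",
        bh_scope: str = "global",
        target_draws: int | None = None,
        n_workers: int = 1,
        random_state: int = 0,
    ):
        self.subsamp_iter = subsamp_iter
        self.subsamp_size = subsamp_size
        self.sig_level = sig_level
        self.p_adj_method = p_adj_method
        self.metric = metric
        self.bh_scope = bh_scope
        self.target_draws = target_draws
        self.n_workers = n_workers
        self.random_state = random_state

    def _params(self) -> MatchParams:
        return MatchParams(
            subsamp_iter=self.subsamp_iter,
            subsamp_size=self.subsamp_size,
            sig_level=self.sig_level,
            p_adj_method=self.p_adj_method,
            metric=self.metric,
            seed=self.random_state,
            n_workers=self.n_workers,
            bh_scope=self.bh_scope,
            target_draws=self.target_draws,
        )

    def fit(self, X, y):
        """Store the reference: X is cells x markers (normalized), y the
        reference cluster label of each cell."""
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.reference_ = _as_gem(X, "ref")
        self.reference_labels_ = _as_labeling(y, "ref", X.shape[0])
        self.classes_ = np.array(self.reference_labels_.clusters, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _query(self, X, query_labels):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return _as_gem(X, "qry"), _as_labeling(query_labels, "qry", X.shape[0])

    def match_pvalues(self, X, query_labels=None, adjusted: bool = True) -> PValueMatrix:
        raise NotImplementedError


class CellToClusterMatcher(_BaseMatcher, ClassifierMixin):
    """Assign each query cell a reference cell type, or UNASSIGNED.

    ``fit(X_ref, y_ref)`` stores the reference atlas; ``predict(X_query,
    query_labels=...)`` runs the iterative subsampled Friedman-Rafsky
    matching and returns one matched reference cluster (or UNASSIGNED) per
    query cell.  ``match_pvalues`` exposes the underlying C x K matrix.
    """

    def match_pvalues(self, X, query_labels=None, adjusted: bool = True) -> PValueMatrix:
        q, ql = self._query(X, query_labels)
        raw = match_cell_to_cluster(
            q, self.reference_, ql, self.reference_labels_, self._params()
        )
        return adjust_pvalues(raw, self.p_adj_method) if adjusted else raw

    def predict(self, X, query_labels=None) -> np.ndarray:
        pvm = self.match_pvalues(X, query_labels)
        calls = assign_matches(pvm, self.sig_level)
        return calls["matched"].to_numpy(dtype=object)

    def score(self, X, y, query_labels=None) -> float:
        """Fraction of cells whose call equals the true label in ``y``."""
        return float(np.mean(self.predict(X, query_labels) == np.asarray(y, dtype=object)))


class ClusterToClusterMatcher(_BaseMatcher):
    """Match whole query clusters to reference clusters by median p-value."""

    def match_pvalues(self, X, query_labels=None, adjusted: bool = True) -> PValueMatrix:
        q, ql = self._query(X, query_labels)
        raw = match_cluster_to_cluster(
            q, self.reference_, ql, self.reference_labels_, self._params()
        )
        return adjust_pvalues(raw, self.p_adj_method) if adjusted else raw

    def predict(self, X, query_labels=None) -> pd.DataFrame:
        """Per query cluster: matched reference cluster or UNASSIGNED."""
        pvm = self.match_pvalues(X, query_labels)
        return assign_matches(pvm, self.sig_level)


class PlatformNormalizer(TransformerMixin, BaseEstimator):
    """Min-max rescaling plus optional cluster-summary weighting.

    Stateless across datasets (each dataset is rescaled against its own
    gene maxima, as the cross-platform procedure prescribes); ``fit``
    records the cluster labels used by the weighting step.
    """

    def __init__(self, norm_by: str = "none", weight: bool = False):
        self.norm_by = norm_by
        self.weight = weight

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.labels_ = None if y is None else np.asarray(y)
        NormalizationConfig(norm_by=self.norm_by if self.norm_by != "none" else "none")
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        gem = _as_gem(check_array(X, dtype=float), "c", layer="counts")
        out = minmax_rescale(gem)
        if self.weight and self.norm_by != "none":
            if self.labels_ is None or len(self.labels_) != gem.n_cells:
                raise ValueError("weighting requires per-cell labels passed to fit(X, y)")
            labeling = _as_labeling(self.labels_, "c", gem.n_cells)
            out = weight_by_cluster_summary(out, labeling, self.norm_by)
        return out.values.T
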