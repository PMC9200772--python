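import numpy as np
import pandas as pd
import pytest

from mstmatch import (
    CellToClusterMatcher,
    ClusterLabeling,
    ClusterToClusterMatcher,
    GeneExpressionMatrix,
    MatchParams,
    PValueMatrix,
    UNASSIGNED,
    adjust_pvalues,
    assign_matches,
    cell2cluster_proportions,
    match_cell_to_cluster,
    match_cluster_to_cluster,
    two_way_match,
)
from mstmatch._core import iterate_pair, pair_rng


def _dataset(rng, centers, cells_per_cluster=30, p=6, scale=0.05, prefix="c"):
    """Well-separated clusters at the given unit-cube corners."""
    values, cells, labels = [], [], []
    for name, center in centers.items():
        pts = rng.normal(scale=scale, size=(cells_per_cluster, p)) + center
        values.append(np.clip(pts, 0, 1))
        for i in range(cells_per_cluster):
            cells.append(f"{prefix}_{name}_{i}")
            labels.append(name)
    gem = GeneExpressionMatrix(
        [f"g{i}" for i in range(p)], cells, np.vstack(values).T, layer="normalized"
    )
    return gem, ClusterLabeling(cells, labels)


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(3)
    centers = {
        "A": np.r_[0.9, 0.9, 0, 0, 0, 0],
        "B": np.r_[0, 0, 0.9, 0.9, 0, 0],
        "C": np.r_[0, 0, 0, 0, 0.9, 0.9],
    }
    q = _dataset(rng, centers, prefix="q")
    r = _dataset(rng, centers, prefix="r")
    return q, r


FAST = MatchParams(subsamp_iter=150, subsamp_size=10, seed=9)


class TestCellToCluster:
    def test_self_match_recovers_labels(self, separated):
        (q, ql), (r, rl) = separated
        raw = match_cell_to_cluster(q, r, ql, rl, FAST)
        assert raw.scheme == "cell2cluster" and not raw.adjusted
        calls = assign_matches(adjust_pvalues(raw), 0.1)
        truth = [ql.cluster_of[str(u)] for u in calls["unit"]]
        assert (calls["matched"] == truth).mean() >= 0.95

    def test_max_update_semantics_match_explicit_loop(self, separated):
        """The vectorized accumulation equals a plain python max-update."""
        (q, ql), (r, rl) = separated
        raw = match_cell_to_cluster(q, r, ql, rl, FAST)
        qv, rv = q.values.T, r.values.T
        for k, rc in enumerate(rl.clusters):
            for j, qc in enumerate(ql.clusters):
                pv, drawn = iterate_pair(
                    qv[ql.indices_of(qc)], rv[rl.indices_of(rc)],
                    FAST.subsamp_size, FAST.subsamp_iter, FAST.metric,
                    pair_rng(FAST.seed, j, k),
                )
                expect = {}
                qcells = ql.indices_of(qc)
                for i in range(FAST.subsamp_iter):
                    for c in drawn[i]:
                        g = q.cell_ids[qcells[c]]
                        expect[g] = max(expect.get(g, -1), pv[i])
                for g, val in expect.items():
                    assert raw.values.loc[g, rc] == pytest.approx(val)

    def test_single_iteration_shares_p_and_leaves_na(self, separated):
        (q, ql), (r, rl) = separated
        params = MatchParams(subsamp_iter=1, subsamp_size=10, seed=4)
        raw = match_cell_to_cluster(q, r, ql, rl, params)
        col = raw.values.iloc[:, 0]
        cov = raw.coverage.iloc[:, 0]
        assert ((cov == 0) == col.isna()).all()
        drawn_ps = col[cov > 0]
        # each query cluster contributes one draw of 10 cells sharing one p
        assert (cov > 0).sum() == 10 * len(ql.clusters)
        assert drawn_ps.groupby(
            [ql.cluster_of[str(i)] for i in drawn_ps.index]
        ).nunique().max() == 1

    def test_trajectories_non_decreasing_in_iterations(self, separated):
        """Max-updated p per cell can only grow as iterations accumulate."""
        (q, ql), (r, rl) = separated
        short = match_cell_to_cluster(
            q, r, ql, rl, MatchParams(subsamp_iter=40, subsamp_size=10, seed=9)
        )
        long = match_cell_to_cluster(
            q, r, ql, rl, MatchParams(subsamp_iter=150, subsamp_size=10, seed=9)
        )
        a = short.values.to_numpy()
        b = long.values.to_numpy()
        both = np.isfinite(a) & np.isfinite(b)
        assert (b[both] >= a[both] - 1e-15).all()

    def test_deterministic_and_worker_invariant(self, separated):
        (q, ql), (r, rl) = separated
        p1 = MatchParams(subsamp_iter=40, seed=7, n_workers=1)
        p2 = MatchParams(subsamp_iter=40, seed=7, n_workers=2)
        a = match_cell_to_cluster(q, r, ql, rl, p1)
        b = match_cell_to_cluster(q, r, ql, rl, p1)
        c = match_cell_to_cluster(q, r, ql, rl, p2)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.values, c.values)

    def test_small_cluster_draw_shrinks_with_warning(self, separated):
        (q, ql), (r, rl) = separated
        keep = ql.cell_ids[:35]  # cluster A=30 cells, B=5 cells
        sub, idx = ClusterLabeling(keep, [ql.cluster_of[c] for c in keep]), None
        qs = q.subset_cells(range(35))
        with pytest.warns(UserWarning, match="draw size reduced"):
            raw = match_cell_to_cluster(qs, r, sub, rl, FAST)
        assert raw.values.shape == (35, 3)

    def test_tiny_cluster_skipped_with_warning(self, separated):
        (q, ql), (r, rl) = separated
        keep = ql.cell_ids[:32]  # cluster B keeps 2 cells -> skipped
        sub = ClusterLabeling(keep, [ql.cluster_of[c] for c in keep])
        qs = q.subset_cells(range(32))
        with pytest.warns(UserWarning, match="skipped"):
            raw = match_cell_to_cluster(qs, r, sub, rl, FAST)
        b_rows = raw.values.loc[[c for c in keep if ql.cluster_of[c] == "B"]]
        assert b_rows.isna().all().all()


class TestClusterToCluster:
    def test_self_match_diagonal_dominates(self, separated):
        (q, ql), (r, rl) = separated
        raw = match_cluster_to_cluster(q, r, ql, rl, FAST)
        adj = adjust_pvalues(raw)
        for cl in ql.clusters:
            assert adj.values.loc[cl, cl] > 0.1
            off = adj.values.loc[cl].drop(cl)
            assert (off < 0.1).all()

    def test_median_is_used(self, separated, monkeypatch):
        (q, ql), (r, rl) = separated
        import mstmatch.matching as m

        recorded = {}
        orig = m.iterate_pair

        def spy(*a, **k):
            pv, drawn = orig(*a, **k)
            recorded.setdefault("pv", pv)
            return pv, drawn

        monkeypatch.setattr(m, "iterate_pair", spy)
        raw = match_cluster_to_cluster(q, r, ql, rl, FAST)
        assert raw.values.iloc[0, 0] == pytest.approx(np.median(recorded["pv"]))

    def test_deterministic(self, separated):
        (q, ql), (r, rl) = separated
        a = match_cluster_to_cluster(q, r, ql, rl, FAST)
        b = match_cluster_to_cluster(q, r, ql, rl, FAST)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_schemes_agree_in_bulk(self, separated):
        """Per-cluster median of cell-level p tracks the cluster-level median."""
        (q, ql), (r, rl) = separated
        params = MatchParams(subsamp_iter=400, subsamp_size=10, seed=2)
        cells = match_cell_to_cluster(q, r, ql, rl, params)
        clusters = match_cluster_to_cluster(q, r, ql, rl, params)
        for l in ql.clusters:
            rows = [c for c in q.cell_ids if ql.cluster_of[c] == l]
            for k in rl.clusters:
                cell_med = np.nanmedian(cells.values.loc[rows, k])
                cluster_p = clusters.values.loc[l, k]
                if l == k:
                    # matching pair: max-update drives cell-level p toward 1
                    # while the cluster scheme keeps the null median; both
                    # sit clearly above the significance threshold
                    assert cell_med >= 0.1 and cluster_p >= 0.1
                else:
                    # separated pair: both schemes agree the p is tiny
                    assert abs(cell_med - cluster_p) <= 0.15
                    assert cell_med < 0.1 and cluster_p < 0.1


def _pvm(values, scheme="cell2cluster", adjusted=False, **meta):
    df = pd.DataFrame(
        np.atleast_2d(values),
        index=[f"u{i}" for i in range(np.atleast_2d(values).shape[0])],
        columns=[f"R{j}" for j in range(np.atleast_2d(values).shape[1])],
    )
    return PValueMatrix(df, scheme=scheme, adjusted=adjusted, meta=meta)


class TestAdjustAndAssign:
    def test_bh_closed_form(self):
        adj = adjust_pvalues(_pvm([[0.01, 0.02, 0.03, 0.04]]))
        np.testing.assert_allclose(adj.values.to_numpy(), 0.04)
        assert adj.adjusted

    def test_bh_all_ones_and_singleton(self):
        np.testing.assert_allclose(
            adjust_pvalues(_pvm([[1.0, 1.0, 1.0]])).values.to_numpy(), 1.0
        )
        assert adjust_pvalues(_pvm([[0.031]])).values.iloc[0, 0] == pytest.approx(0.031)

    def test_bh_passes_na_and_never_decreases(self, rng):
        vals = rng.random((8, 4))
        vals[vals < 0.25] = np.nan
        adj = adjust_pvalues(_pvm(vals))
        out = adj.values.to_numpy()
        assert np.isnan(out).sum() == np.isnan(vals).sum()
        ok = np.isfinite(vals)
        assert (out[ok] >= vals[ok] - 1e-15).all()
        assert out[ok].max() <= 1.0

    def test_assign_below_threshold_is_unassigned(self):
        calls = assign_matches(_pvm([[0.05, 0.02, 0.08]], adjusted=True), 0.1)
        assert calls.loc[0, "matched"] == UNASSIGNED
        assert calls.loc[0, "confidence"] == pytest.approx(0.08)

    def test_assign_argmax_and_confidence(self):
        calls = assign_matches(_pvm([[0.05, 0.6, 0.08]], adjusted=True), 0.1)
        assert calls.loc[0, "matched"] == "R1"
        assert calls.loc[0, "confidence"] == pytest.approx(0.6)

    def test_assign_tie_takes_first_column_and_flags(self):
        calls = assign_matches(_pvm([[0.6, 0.6]], adjusted=True), 0.1)
        assert calls.loc[0, "matched"] == "R0"
        assert bool(calls.loc[0, "tie"])

    def test_assign_all_na_row_unassigned(self):
        calls = assign_matches(_pvm([[np.nan, np.nan]], adjusted=True), 0.1)
        assert calls.loc[0, "matched"] == UNASSIGNED
        assert np.isnan(calls.loc[0, "confidence"])


class TestProportions:
    def _calls(self, labels, matched):
        df = pd.DataFrame({
            "unit": list(labels.cell_ids), "matched": matched,
            "confidence": 0.5, "tie": False,
        })
        df.attrs["reference_clusters"] = ["A", "B"]
        return df

    def test_unanimous_cluster(self):
        lab = ClusterLabeling([f"c{i}" for i in range(10)], ["Q1"] * 10)
        table = cell2cluster_proportions(self._calls(lab, ["A"] * 10), lab)
        assert table.loc["A", "Q1"] == 1.0
        assert table.loc[UNASSIGNED, "Q1"] == 0.0

    def test_even_split(self):
        lab = ClusterLabeling([f"c{i}" for i in range(10)], ["Q1"] * 10)
        table = cell2cluster_proportions(self._calls(lab, ["A"] * 5 + ["B"] * 5), lab)
        assert table.loc["A", "Q1"] == table.loc["B", "Q1"] == 0.5

    def test_columns_sum_to_one(self, rng):
        lab = ClusterLabeling(
            [f"c{i}" for i in range(40)], [f"Q{i % 3}" for i in range(40)]
        )
        matched = rng.choice(["A", "B", UNASSIGNED], size=40)
        table = cell2cluster_proportions(self._calls(lab, matched), lab)
        np.testing.assert_allclose(table.sum(axis=0), 1.0)
        assert list(table.index)[-1] == UNASSIGNED


class TestTwoWay:
    def _adj(self, values, index, columns):
        df = pd.DataFrame(values, index=index, columns=columns)
        return PValueMatrix(df, scheme="cluster2cluster", adjusted=True)

    def test_conjunction_rule(self):
        fwd = self._adj([[0.5, 0.01]], ["L1"], ["K1", "K2"])
        rev = self._adj([[0.5], [0.9]], ["K1", "K2"], ["L1"])
        assert two_way_match(fwd, rev, 0.1) == {("L1", "K1")}

    def test_one_direction_fails(self):
        fwd = self._adj([[0.5]], ["L1"], ["K1"])
        rev = self._adj([[0.01]], ["K1"], ["L1"])
        assert two_way_match(fwd, rev, 0.1) == set()

    def test_label_mismatch_errors(self):
        fwd = self._adj([[0.5]], ["L1"], ["K1"])
        rev = self._adj([[0.5]], ["K9"], ["L1"])
        with pytest.raises(Exception, match="transposed"):
            two_way_match(fwd, rev, 0.1)

    def test_self_match_diagonal_all_matched(self, separated):
        (q, ql), (r, rl) = separated
        fwd = adjust_pvalues(match_cluster_to_cluster(q, r, ql, rl, FAST))
        rev = adjust_pvalues(match_cluster_to_cluster(r, q, rl, ql, FAST))
        pairs = two_way_match(fwd, rev, 0.1)
        assert {(c, c) for c in ql.clusters} <= pairs


class TestEstimators:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = CellToClusterMatcher(subsamp_iter=11, random_state=3)
        params = est.get_params()
        assert params["subsamp_iter"] == 11
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(metric="cosine")
        assert est.metric == "cosine"

    def test_cell_matcher_fit_predict(self, separated):
        (q, ql), (r, rl) = separated
        est = CellToClusterMatcher(subsamp_iter=150, random_state=9)
        est.fit(r.values.T, rl.labels)
        assert list(est.classes_) == ["A", "B", "C"]
        pred = est.predict(q.values.T, query_labels=ql.labels)
        truth = np.asarray(ql.labels, dtype=object)
        assert (pred == truth).mean() >= 0.95
        assert est.score(q.values.T, ql.labels, query_labels=ql.labels) >= 0.95

    def test_cluster_matcher_predict(self, separated):
        (q, ql), (r, rl) = separated
        est = ClusterToClusterMatcher(subsamp_iter=150, random_state=9)
        est.fit(r.values.T, rl.labels)
        calls = est.predict(q.values.T, query_labels=ql.labels)
        assert dict(zip(calls["unit"], calls["matched"])) == {
            "A": "A", "B": "B", "C": "C"
        }

    def test_platform_normalizer_matches_functions(self, rng):
        from mstmatch import PlatformNormalizer, minmax_rescale
        from mstmatch.data import GeneExpressionMatrix

        X = rng.random((12, 5))
        est = PlatformNormalizer().fit(X)
        out = est.transform(X)
        gem = GeneExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"c{i}" for i in range(12)], X.T
        )
        np.testing.assert_allclose(out, minmax_rescale(gem).values.T)
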