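"""Sparse Pearson vs dense oracle, null thresholds, candidate rule, bootstraps."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import dense_pearson
from stabmark import AnalysisConfig, ClusterAnnotation, Comparison, ExpressionMatrix
from stabmark.coexpression import (
    CoexpressionEdge,
    ThresholdSet,
    bootstrap_edges,
    estimate_null_thresholds,
    find_candidate_edges,
    sparse_pearson,
)
from stabmark.core_selection import CoreGeneResult


def _expr_from_dense(X, scale="lognorm"):
    g, c = X.shape
    return ExpressionMatrix(
        sp.csr_matrix(X), [f"g{i}" for i in range(g)], [f"c{j}" for j in range(c)],
        scale=scale,
    )


class TestSparsePearson:
    def test_self_correlation_is_one(self, rng):
        X = rng.poisson(2.0, size=(5, 20)).astype(float)
        expr = _expr_from_dense(X)
        r = sparse_pearson(expr, ["g0"], ["g0"])
        assert r[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([x, -x + 5.0, np.ones(4)])
        r = sparse_pearson(_expr_from_dense(X), ["g0"], ["g1"])
        assert r[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_dense_oracle_on_random_sparse(self, rng):
        X = np.asarray(
            sp.random(8, 30, density=0.4, random_state=7, format="csr").todense()
        )
        expr = _expr_from_dense(X)
        r = sparse_pearson(expr, list(expr.gene_ids), list(expr.gene_ids))
        for i in range(8):
            for j in range(8):
                expected = dense_pearson(X[i], X[j])
                if np.isnan(expected):
                    assert np.isnan(r[i, j])
                else:
                    assert r[i, j] == pytest.approx(expected, abs=1e-10)

    def test_cell_subset_matches_oracle(self, rng):
        X = rng.normal(size=(4, 25))
        expr = _expr_from_dense(X)
        cells = [f"c{j}" for j in range(0, 25, 2)]
        r = sparse_pearson(expr, ["g1"], ["g3"], cells)
        assert r[0, 0] == pytest.approx(
            dense_pearson(X[1, ::2], X[3, ::2]), abs=1e-10
        )

    def test_zero_variance_gene_is_nan(self):
        X = np.vstack([np.ones(10), np.arange(10, dtype=float)])
        r = sparse_pearson(_expr_from_dense(X), ["g0"], ["g1"])
        assert np.isnan(r[0, 0])

    def test_empty_gene_list(self, small_counts):
        r = sparse_pearson(small_counts, [], ["g0"])
        assert r.shape == (0, 1)

    def test_too_few_cells_rejected(self, small_counts):
        with pytest.raises(ValueError, match="3 cells"):
            sparse_pearson(small_counts, ["g0"], ["g1"], ["c0", "c1"])


class TestNullThresholds:
    def test_symmetric_quantiles_on_symmetric_pool(self):
        # quantile symmetry checked directly on a hand-built pool
        pool = np.concatenate([np.arange(-0.9, 1.0, 0.1)])
        hi = np.quantile(pool, 0.975)
        lo = np.quantile(pool, 0.025)
        assert hi == pytest.approx(-lo, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 60)).clip(min=0)
        expr = _expr_from_dense(X)
        ann = ClusterAnnotation(
            labels={c: ("A" if j < 30 else "B") for j, c in enumerate(expr.cell_ids)}
        )
        cfg = AnalysisConfig(n_null_genes=20, n_null_rounds=4, seed=3)
        cmp = Comparison("one_vs_all", "A")
        t1 = estimate_null_thresholds(expr, ann, cmp, cfg, np.random.default_rng(9))
        t2 = estimate_null_thresholds(expr, ann, cmp, cfg, np.random.default_rng(9))
        assert (t1.corr_pos, t1.corr_neg, t1.diff_pos, t1.diff_neg) == (
            t2.corr_pos, t2.corr_neg, t2.diff_pos, t2.diff_neg
        )

    def test_matches_monte_carlo_quantile_on_iid_data(self):
        # i.i.d. normal expression: the null 97.5th percentile of sample
        # correlation at n cells, estimated by the pipeline, must agree with a
        # direct Monte-Carlo oracle using an independent RNG stream
        n_cells = 200
        gen = np.random.default_rng(101)
        X = gen.normal(size=(300, n_cells))
        expr = _expr_from_dense(X)
        ann = ClusterAnnotation(
            labels={
                c: ("A" if j < n_cells // 2 else "B")
                for j, c in enumerate(expr.cell_ids)
            }
        )
        cfg = AnalysisConfig(n_null_genes=150, n_null_rounds=10, seed=5)
        th = estimate_null_thresholds(
            expr, ann, Comparison("one_vs_all", "A"), cfg,
            np.random.default_rng(17),
        )
        oracle_rng = np.random.default_rng(999)  # independent stream
        sims = np.empty(4000)
        for k in range(sims.size):
            a = oracle_rng.normal(size=n_cells)
            b = oracle_rng.normal(size=n_cells)
            sims[k] = dense_pearson(a, b)
        oracle_hi = np.quantile(sims, 0.975)
        assert th.corr_pos == pytest.approx(oracle_hi, rel=0.15)
        assert th.corr_neg == pytest.approx(-oracle_hi, rel=0.2, abs=0.02)


class TestCandidateRule:
    TH = ThresholdSet(corr_pos=0.3, corr_neg=-0.3, diff_pos=0.4, diff_neg=-0.4)

    def test_rule_via_edge_filter(self):
        from stabmark.coexpression import _edge_significant

        r_all = np.array([[0.5, 0.1, 0.0, np.nan]])
        diff = np.array([[0.0, 0.6, 0.1, np.nan]])
        sig = _edge_significant(r_all, diff, self.TH)
        assert sig.tolist() == [[True, True, False, False]]

    def test_candidates_on_planted_correlation(self):
        rng = np.random.default_rng(2)
        n = 60
        base = rng.normal(size=n)
        X = np.vstack([
            base,                           # core gene
            base + rng.normal(0, 0.2, n),   # strongly correlated partner
            rng.normal(size=n),             # independent gene
        ]).clip(min=0)
        expr = _expr_from_dense(X + 2.0)
        ann = ClusterAnnotation(
            labels={c: ("A" if j < n // 2 else "B")
                    for j, c in enumerate(expr.cell_ids)}
        )
        core = CoreGeneResult(
            Comparison("one_vs_all", "A"), {"g0": 20}, ["g0"], False
        )
        th = ThresholdSet(0.5, -0.5, 0.5, -0.5)
        edges = find_candidate_edges(
            expr, ann, Comparison("one_vs_all", "A"), core, th
        )
        secondaries = {e.secondary for e in edges}
        assert "g1" in secondaries
        assert "g2" not in secondaries
        for e in edges:
            assert e.diff_corr == pytest.approx(e.r_group1 - e.r_group2, abs=1e-12)
            assert e.core != e.secondary


class TestBootstrapEdges:
    def _two_cluster_expr(self, n=300, seed=4):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        planted = 0.8 * base + np.sqrt(1 - 0.64) * rng.normal(size=n)
        X = np.vstack([base, planted, rng.normal(size=n), rng.normal(size=n)])
        expr = _expr_from_dense(X + 3.0)
        ann = ClusterAnnotation(
            labels={c: ("A" if j < n // 2 else "B")
                    for j, c in enumerate(expr.cell_ids)}
        )
        return expr, ann

    def test_planted_pair_retained_null_pair_dropped(self):
        # population r = 0.8 pair survives 60% subsampling; r = 0 pair does not
        for seed in range(5):
            expr, ann = self._two_cluster_expr(seed=seed)
            cmp = Comparison("one_vs_all", "A")
            th = ThresholdSet(0.25, -0.25, 0.35, -0.35)
            candidates = [
                CoexpressionEdge("g0", "g1", 0.8, 0.8, 0.8, 0.0),
                CoexpressionEdge("g0", "g2", 0.0, 0.0, 0.0, 0.0),
            ]
            cfg = AnalysisConfig(n_boot=40, K=32, seed=seed)
            net = bootstrap_edges(
                expr, ann, cmp, candidates, th, cfg,
                rng=np.random.default_rng(seed),
            )
            kept = {(e.core, e.secondary) for e in net.edges}
            assert ("g0", "g1") in kept
            assert ("g0", "g2") not in kept

    def test_perfect_pair_full_support(self):
        expr, ann = self._two_cluster_expr()
        x = np.asarray(expr.values.todense())
        x[1] = x[0] * 2.0  # exact linear copy => r = 1 in every subsample
        expr = _expr_from_dense(x)
        cmp = Comparison("one_vs_all", "A")
        th = ThresholdSet(0.5, -0.5, 0.5, -0.5)
        cfg = AnalysisConfig(n_boot=30, K=24, seed=0)
        net = bootstrap_edges(
            expr, ann, cmp, [CoexpressionEdge("g0", "g1", 1, 1, 1, 0)], th, cfg,
            rng=np.random.default_rng(1),
        )
        assert net.edges and net.edges[0].support == 30

    def test_support_threshold_strict(self):
        # an edge with support == K must be dropped, support > K retained
        expr, ann = self._two_cluster_expr()
        cmp = Comparison("one_vs_all", "A")
        th = ThresholdSet(0.25, -0.25, 0.35, -0.35)
        cfg = AnalysisConfig(n_boot=20, K=20, seed=0)  # support can never exceed K
        net = bootstrap_edges(
            expr, ann, cmp, [CoexpressionEdge("g0", "g1", 0.8, 0.8, 0.8, 0.0)],
            th, cfg, rng=np.random.default_rng(0),
        )
        assert net.edges == []

    def test_raising_k_never_enlarges_network(self):
        expr, ann = self._two_cluster_expr()
        cmp = Comparison("one_vs_all", "A")
        th = ThresholdSet(0.2, -0.2, 0.3, -0.3)
        candidates = [
            CoexpressionEdge("g0", "g1", 0.8, 0.8, 0.8, 0.0),
            CoexpressionEdge("g0", "g2", 0.0, 0.0, 0.0, 0.0),
            CoexpressionEdge("g0", "g3", 0.0, 0.0, 0.0, 0.0),
        ]
        prev = None
        for K in (10, 20, 30, 39):
            cfg = AnalysisConfig(n_boot=40, K=K, seed=0)
            net = bootstrap_edges(
                expr, ann, cmp, candidates, th, cfg,
                rng=np.random.default_rng(3),
            )
            kept = {(e.core, e.secondary) for e in net.edges}
            if prev is not None:
                assert kept <= prev
            prev = kept
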