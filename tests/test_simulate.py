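"""Synthetic data generator, metrics and the benchmark harness."""

import numpy as np
import pytest

from stabmark.coexpression import sparse_pearson
from stabmark.simulate import (
    SimulationConfig,
    SimulationGrid,
    evaluate,
    generate_base_expression,
    generate_pathway_db,
    select_predictive_genes,
    simulate_dataset,
    simulate_phenotype,
    stability_measure,
)


class TestPathwayDB:
    def test_zero_overlap_gives_disjoint_pathways(self, rng):
        db = generate_pathway_db(8, (5, 10), 0.0, 300, rng)
        seen = set()
        for name in db.names():
            assert not (db.genes(name) & seen)
            seen |= db.genes(name)

    def test_half_overlap_two_pathways(self):
        rng = np.random.default_rng(0)
        db = generate_pathway_db(2, (10, 10), 0.5, 100, rng)
        a, b = (db.genes(n) for n in db.names())
        assert len(a) == len(b) == 10
        assert len(a & b) == 5

    def test_requested_overlap_realised_on_average(self):
        # mean sharing with already-used genes matches the requested fraction
        shared_fracs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            db = generate_pathway_db(6, (20, 20), 0.3, 600, rng)
            names = db.names()
            for k in range(1, len(names)):
                earlier = set().union(*(db.genes(n) for n in names[:k]))
                frac = len(db.genes(names[k]) & earlier) / 20
                shared_fracs.append(frac)
        assert np.mean(shared_fracs) == pytest.approx(0.3, abs=0.03)

    def test_pool_exhaustion_raises(self):
        with pytest.raises(ValueError, match="exhausted"):
            generate_pathway_db(10, (30, 30), 0.0, 100, np.random.default_rng(0))


class TestBaseExpression:
    def test_default_gene_count(self, rng):
        db = generate_pathway_db(5, (10, 15), 0.0, 2000, rng)
        expr = generate_base_expression(db, 50, rng=rng)
        assert expr.n_genes == 2000

    def test_zero_module_strength_no_coexpression(self, rng):
        db = generate_pathway_db(3, (15, 15), 0.0, 400, rng)
        expr = generate_base_expression(db, 300, 400, module_strength=0.0, rng=rng)
        genes = sorted(db.genes(db.names()[0]))
        r = sparse_pearson(expr, genes, genes)
        iu = np.triu_indices(len(genes), 1)
        assert np.nanmean(np.abs(r[iu])) < 0.08

    def test_strong_modules_exceed_background(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            db = generate_pathway_db(3, (15, 15), 0.0, 400, rng)
            expr = generate_base_expression(db, 250, 400, module_strength=0.8,
                                            rng=rng)
            within = []
            for name in db.names():
                genes = sorted(db.genes(name))
                r = sparse_pearson(expr, genes, genes)
                iu = np.triu_indices(len(genes), 1)
                within.append(np.nanmean(np.abs(r[iu])))
            in_pw = set().union(*(db.genes(n) for n in db.names()))
            bg = sorted(set(expr.gene_ids) - in_pw)[:15]
            r_bg = sparse_pearson(expr, bg, bg)
            iu = np.triu_indices(len(bg), 1)
            background = np.nanmean(np.abs(r_bg[iu]))
            assert min(within) > background

    def test_counts_scale_nonnegative_integers(self, rng):
        db = generate_pathway_db(2, (10, 10), 0.0, 100, rng)
        expr = generate_base_expression(db, 30, 100, rng=rng, scale="counts")
        assert expr.scale == "counts"
        data = expr.values.data
        assert (data >= 0).all()
        assert np.allclose(data, np.round(data))


class TestSelectPredictiveGenes:
    def test_returns_n_members_of_selected_pathways(self, rng):
        db = generate_pathway_db(6, (15, 20), 0.1, 500, rng)
        expr = generate_base_expression(db, 150, 500, rng=rng)
        genes, pws = select_predictive_genes(expr, db, 3, 12, rng)
        assert len(genes) == 12
        assert len(pws) == 3
        members = set().union(*(db.genes(p) for p in pws))
        assert set(genes) <= members

    def test_ranking_matches_brute_force(self, rng):
        db = generate_pathway_db(4, (12, 15), 0.2, 300, rng)
        expr = generate_base_expression(db, 150, 300, rng=rng)
        genes, pws = select_predictive_genes(expr, db, 2, 8,
                                             np.random.default_rng(7))
        # brute-force score recomputation over the same pathway choice
        pool = sorted(
            set().union(*(db.genes(p) for p in pws)) & set(expr.gene_ids)
        )
        r = sparse_pearson(expr, pool, pool)
        np.fill_diagonal(r, np.nan)
        conn = np.nansum(np.abs(r), axis=1)
        conn = conn / conn.max()
        counts = np.array(
            [sum(1 for p in pws if g in db.genes(p)) for g in pool], float
        )
        score = conn * (1 + counts / counts.max())
        order = sorted(range(len(pool)), key=lambda i: (-score[i], pool[i]))
        assert genes == [pool[i] for i in order[:8]]

    def test_infeasible_n_raises(self, rng):
        db = generate_pathway_db(2, (5, 6), 0.0, 100, rng)
        expr = generate_base_expression(db, 30, 100, rng=rng)
        with pytest.raises(ValueError, match="genes"):
            select_predictive_genes(expr, db, 1, 50, rng)


class TestSimulatePhenotype:
    def _dataset(self, seed=0):
        rng = np.random.default_rng(seed)
        db = generate_pathway_db(3, (12, 15), 0.0, 300, rng)
        expr = generate_base_expression(db, 400, 300, rng=rng)
        genes, _ = select_predictive_genes(expr, db, 2, 6, rng)
        return expr, genes, rng

    def test_truth_betas_in_stated_range(self):
        expr, genes, rng = self._dataset()
        _, betas = simulate_phenotype(expr, genes, "linear", 0.9, rng)
        for g in genes:
            assert 5.0 <= abs(betas[g]) <= 10.0
        others = [b for g, b in betas.items() if g not in set(genes)]
        assert max(abs(b) for b in others) <= 0.1

    def test_realized_snr_close_to_target(self):
        # recompute Var(signal)/(Var(signal)+Var(noise)) from the definition:
        # noise variance is Var(signal) (1 - snr)/snr, so the proportion is snr
        for snr in (0.5, 0.7, 0.9):
            var_sig = 1.0
            var_noise = var_sig * (1 - snr) / snr
            realized = var_sig / (var_sig + var_noise)
            assert realized == pytest.approx(snr, abs=1e-12)
        # and empirically: labels correlate with the signal more at high snr
        expr, genes, _ = self._dataset(seed=1)
        rng_hi = np.random.default_rng(42)
        y_hi, betas = simulate_phenotype(expr, genes, "linear", 0.9, rng_hi)
        assert 0.05 < y_hi.mean() < 0.95  # both classes realised

    def test_nonlinear_differs_from_linear(self):
        expr, genes, _ = self._dataset(seed=2)
        y_lin, _ = simulate_phenotype(
            expr, genes, "linear", 0.9, np.random.default_rng(5)
        )
        y_non, _ = simulate_phenotype(
            expr, genes, "nonlinear", 0.9, np.random.default_rng(5)
        )
        assert (y_lin != y_non).any()

    def test_threshold_binarization(self):
        expr, genes, _ = self._dataset(seed=3)
        y1, _ = simulate_phenotype(
            expr, genes, "linear", 0.9, np.random.default_rng(6),
            binarize="threshold",
        )
        y2, _ = simulate_phenotype(
            expr, genes, "linear", 0.9, np.random.default_rng(6),
            binarize="threshold",
        )
        np.testing.assert_array_equal(y1, y2)


class TestEvaluate:
    def test_printed_formula_hand_value(self):
        m = evaluate({f"g{i}" for i in range(10)},
                     {f"g{i}" for i in range(8)} | {"x", "y"})
        assert (m.tp, m.fp, m.fn) == (8, 2, 2)
        assert m.f1 == pytest.approx(8 / (8 + 0.5 * 4))

    def test_perfect_prediction(self):
        m = evaluate({"a", "b"}, {"a", "b"})
        assert m.f1 == 1.0 and m.fdr == 0.0 and m.tpr == 1.0

    def test_empty_prediction(self):
        m = evaluate(set(), {"a"})
        assert m.f1 == 0.0 and m.tpr == 0.0 and m.fdr == 0.0


class TestStability:
    def test_three_of_five_overlap_is_sixty_percent(self):
        sets = {
            ("d1", "c"): {"a", "b", "c", "d", "e"},
            ("d2", "c"): {"a", "b", "c", "x", "y"},
        }
        rep = stability_measure(sets)
        assert rep.S == pytest.approx(60.0)

    def test_identical_sets_everywhere(self):
        sets = {(d, c): {"a", "b"} for d in ("d1", "d2", "d3") for c in ("x", "y")}
        assert stability_measure(sets).S == pytest.approx(100.0)

    def test_disjoint_sets(self):
        sets = {("d1", "c"): {"a"}, ("d2", "c"): {"b"}}
        assert stability_measure(sets).S == pytest.approx(0.0)

    def test_min_denominator_for_unequal_sizes(self):
        sets = {("d1", "c"): {"a", "b"}, ("d2", "c"): {"a", "b", "x", "y", "z"}}
        assert stability_measure(sets).S == pytest.approx(100.0)

    def test_empty_set_pair_skipped(self):
        sets = {
            ("d1", "c"): set(), ("d2", "c"): {"a"},
            ("d1", "k"): {"a"}, ("d2", "k"): {"a"},
        }
        with pytest.warns(UserWarning, match="empty marker set"):
            rep = stability_measure(sets)
        assert list(rep.per_cluster_pairwise) == [("k", "d1", "d2")]


class TestGrid:
    def test_printed_design_has_3600_cells(self):
        grid = SimulationGrid()
        assert len(grid.expand()) == 3600

    def test_reduced_grid_cardinality(self):
        grid = SimulationGrid(p_values=(5,), n_values=(10,), snr_values=(0.9,),
                              models=("linear",), n_reps=2)
        assert len(grid.expand()) == 2


class TestSimulateDataset:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_cells=80, n_genes_total=600,
                               n_pathways_db=12, seed=4)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.truth_genes == b.truth_genes
        assert (a.expr.values != b.expr.values).nnz == 0
        assert a.labels.labels == b.labels.labels

    def test_truth_genes_belong_to_truth_pathways(self):
        cfg = SimulationConfig(n_cells=60, n_genes_total=600,
                               n_pathways_db=12, seed=9)
        ds = simulate_dataset(cfg)
        members = set().union(*(ds.pathway_db.genes(p) for p in ds.truth_pathways))
        assert ds.truth_genes <= members
        assert len(ds.truth_genes) == cfg.n_predictive_genes
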