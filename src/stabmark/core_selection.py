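"""Core-gene selection by stability-filtered L1-penalised logistic regression.

A binary contrast (one cluster vs another, or vs all remaining cells) is fit
repeatedly on random 70/30 train/test splits that preserve the cluster
composition of the input.  Genes whose coefficient is non-zero are recorded
per iteration; genes selected in strictly more than ``theta`` of the
``n_lasso_iter`` iterations become the comparison's *core genes*.  When no
gene clears the threshold, the most frequently selected genes (default five)
are kept instead and the result is flagged as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .config import ALL, AnalysisConfig, Comparison
from .io import ClusterAnnotation, ExpressionMatrix, balanced_subsample

__all__ = ["CoreGeneResult", "comparison_cells", "select_core_genes"]


@dataclass
class CoreGeneResult:
    comparison: Comparison
    selection_counts: dict[str, int]
    core_genes: list[str]
    fallback_used: bool

    def counts_array(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.selection_counts.get(g, 0) for g in gene_ids])


def comparison_cells(
    ann: ClusterAnnotation, cmp: Comparison
) -> tuple[list[str], list[str]]:
    """Target and reference cell ids for a comparison (input order preserved)."""
    if cmp.target not in ann.clusters:
        raise ValueError(f"unknown target cluster {cmp.target!r}")
    target = ann.cells_of(cmp.target)
    if cmp.reference == ALL:
        reference = ann.cells_not_of(cmp.target)
    else:
        if cmp.reference not in ann.clusters:
            raise ValueError(f"unknown reference cluster {cmp.reference!r}")
        reference = ann.cells_of(cmp.reference)
    return target, reference


def _stratified_split(
    clusters: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into train/test keeping each cluster's share of cells."""
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for cl in np.unique(clusters):
        idx = np.flatnonzero(clusters == cl)
        idx = rng.permutation(idx)
        n_train = max(1, min(len(idx) - 1, int(round(train_frac * len(idx)))))
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.concatenate(train), np.concatenate(test)


def _core_from_counts(
    counts: dict[str, int], theta: int, fallback_size: int
) -> tuple[list[str], bool]:
    core = sorted([g for g, c in counts.items() if c > theta])
    if core:
        return core, False
    nonzero = [(g, c) for g, c in counts.items() if c > 0]
    # highest count first; ties broken lexicographically for determinism
    nonzero.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in nonzero[:fallback_size]], True


def select_core_genes(
    expr: ExpressionMatrix,
    ann: ClusterAnnotation,
    cmp: Comparison,
    cfg: AnalysisConfig,
) -> CoreGeneResult:
    if expr.scale != "lognorm":
        raise ValueError("core selection requires lognorm-scale expression")
    target_cells, reference_cells = comparison_cells(ann, cmp)
    if len(target_cells) < cfg.min_target_cells:
        raise ValueError(
            f"target cluster {cmp.target!r} has {len(target_cells)} cells "
            f"(< {cfg.min_target_cells})"
        )
    cells = target_cells + reference_cells
    cell_idx = expr.cell_indices(cells)
    X_full = sp.csc_matrix(expr.values[:, cell_idx].T)  # cells x genes
    y_full = np.zeros(len(cells), dtype=int)
    y_full[: len(target_cells)] = 1
    cluster_of = np.array([ann.labels[c] for c in cells])

    # genes never expressed in this comparison's cells can never be selected
    expressed = np.flatnonzero(np.diff(X_full.indptr) > 0)
    X_full = sp.csr_matrix(X_full[:, expressed])
    gene_ids = [expr.gene_ids[expressed[j]] for j in range(expressed.size)]

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    counts = np.zeros(len(gene_ids), dtype=int)
    c_grid = np.geomspace(cfg.lambda_min, cfg.lambda_max, cfg.n_lambda)

    sub_ann = ClusterAnnotation(
        labels={c: ann.labels[c] for c in cells}
    ) if cfg.max_cells_per_cluster else None

    for _ in range(cfg.n_lasso_iter):
        if cfg.max_cells_per_cluster:
            keep = balanced_subsample(sub_ann, cfg.max_cells_per_cluster, rng)
            pool = np.flatnonzero([c in keep for c in cells])
        else:
            pool = np.arange(len(cells))
        if y_full[pool].min() == y_full[pool].max():
            raise ValueError("a comparison group is empty after subsampling")
        tr, te = _stratified_split(cluster_of[pool], cfg.train_frac, rng)
        tr, te = pool[tr], pool[te]
        if len(np.unique(y_full[tr])) < 2 or len(np.unique(y_full[te])) < 2:
            continue  # degenerate split; iteration contributes no selections
        X_tr, y_tr = X_full[tr], y_full[tr]
        X_te, y_te = X_full[te], y_full[te]
        seed = int(rng.integers(2**31 - 1))
        losses, ses, coefs = [], [], []
        for C in c_grid:
            model = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", max_iter=200,
                tol=1e-2, random_state=seed,
            )
            model.fit(X_tr, y_tr)
            p = np.clip(model.predict_proba(X_te)[:, 1], 1e-12, 1 - 1e-12)
            cell_loss = -(y_te * np.log(p) + (1 - y_te) * np.log(1 - p))
            losses.append(cell_loss.mean())
            ses.append(cell_loss.std(ddof=1) / np.sqrt(len(y_te)))
            coefs.append(model.coef_.ravel())
        # one-SE rule: sparsest penalty whose held-out deviance is within one
        # standard error of the best, as in glmnet's lambda.1se
        best = int(np.argmin(losses))
        cutoff = losses[best] + ses[best]
        chosen = next(i for i in range(len(c_grid)) if losses[i] <= cutoff)
        counts[coefs[chosen] != 0] += 1

    selection_counts = {g: int(c) for g, c in zip(gene_ids, counts)}
    # unexpressed genes keep a count of zero
    for g in expr.gene_ids:
        selection_counts.setdefault(g, 0)
    core, fallback = _core_from_counts(selection_counts, cfg.theta, cfg.fallback_size)
    return CoreGeneResult(cmp, selection_counts, core, fallback)
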