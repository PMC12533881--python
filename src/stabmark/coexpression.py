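"""Sparse co-expression networks around core genes.

Pearson correlations are computed directly from sparse cross-products, so the
full gene x cell matrix is never densified.  Significance thresholds for
plain and differential correlation are calibrated per comparison from a
permutation null (random gene panels), and candidate core-secondary edges are
stabilised by re-testing them on repeated 60% cluster-stratified subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .config import AnalysisConfig, Comparison
from .core_selection import CoreGeneResult, comparison_cells
from .io import ClusterAnnotation, ExpressionMatrix, balanced_subsample

__all__ = [
    "ThresholdSet",
    "CoexpressionEdge",
    "CoexpressionNetwork",
    "sparse_pearson",
    "estimate_null_thresholds",
    "find_candidate_edges",
    "bootstrap_edges",
]


@dataclass
class ThresholdSet:
    """Null-calibrated significance bands for plain and differential correlation."""

    corr_pos: float
    corr_neg: float
    diff_pos: float
    diff_neg: float
    comparison: Comparison | None = None

    def __post_init__(self) -> None:
        if not (self.corr_pos >= 0 >= self.corr_neg):
            raise ValueError("corr thresholds must bracket zero")
        if not (self.diff_pos >= 0 >= self.diff_neg):
            raise ValueError("diff thresholds must bracket zero")


@dataclass
class CoexpressionEdge:
    core: str
    secondary: str
    r_all: float
    r_group1: float
    r_group2: float
    diff_corr: float
    support: int = 0


@dataclass
class CoexpressionNetwork:
    comparison: Comparison
    edges: list[CoexpressionEdge] = field(default_factory=list)

    def secondaries_of(self, core: str) -> list[str]:
        return [e.secondary for e in self.edges if e.core == core]

    def core_genes(self) -> list[str]:
        seen: list[str] = []
        for e in self.edges:
            if e.core not in seen:
                seen.append(e.core)
        return seen


def _moments(X: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row means and standard deviations (population, ddof=0) of a sparse matrix."""
    n = X.shape[1]
    mu = np.asarray(X.sum(axis=1)).ravel() / n
    ex2 = np.asarray(X.multiply(X).sum(axis=1)).ravel() / n
    var = np.maximum(ex2 - mu**2, 0.0)
    return mu, np.sqrt(var)


def sparse_pearson(
    expr: ExpressionMatrix,
    rows_a: list[str] | np.ndarray,
    rows_b: list[str] | np.ndarray,
    cells: list[str] | np.ndarray | None = None,
) -> np.ndarray:
    """Pearson correlation of every gene in ``rows_a`` with every gene in ``rows_b``.

    Works from sparse cross-products: r = (E[xy] - E[x]E[y]) / (sd_x sd_y).
    Rows may be gene ids or integer row indices; ``cells`` likewise ids or
    column indices (default: all cells).  Zero-variance genes yield NaN.
    """
    ia = _as_gene_idx(expr, rows_a)
    ib = _as_gene_idx(expr, rows_b)
    if ia.size == 0 or ib.size == 0:
        return np.empty((ia.size, ib.size))
    if cells is None:
        cols = np.arange(expr.n_cells)
    else:
        cols = _as_cell_idx(expr, cells)
    if cols.size < 3:
        raise ValueError("need at least 3 cells for correlation")
    sub = sp.csr_matrix(expr.values[:, cols])
    return _pearson_from_sparse(sub[ia], sub[ib])


def _pearson_from_sparse(A: sp.spmatrix, B: sp.spmatrix) -> np.ndarray:
    n = A.shape[1]
    mu_a, sd_a = _moments(A)
    mu_b, sd_b = _moments(B)
    cross = np.asarray((A @ B.T).todense()) / n
    cov = cross - np.outer(mu_a, mu_b)
    denom = np.outer(sd_a, sd_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _as_gene_idx(expr: ExpressionMatrix, rows) -> np.ndarray:
    rows = list(rows)
    if rows and isinstance(rows[0], str):
        return expr.gene_indices(rows)
    return np.asarray(rows, dtype=int)


def _as_cell_idx(expr: ExpressionMatrix, cells) -> np.ndarray:
    cells = list(cells)
    if cells and isinstance(cells[0], str):
        return expr.cell_indices(cells)
    return np.asarray(cells, dtype=int)


def _maybe_capped_cells(
    ann: ClusterAnnotation,
    cmp: Comparison,
    cfg: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Comparison cells after the optional per-cluster cap."""
    target, reference = comparison_cells(ann, cmp)
    if cfg.max_cells_per_cluster:
        sub = ClusterAnnotation(
            labels={c: ann.labels[c] for c in target + reference}
        )
        keep = balanced_subsample(sub, cfg.max_cells_per_cluster, rng)
        target = [c for c in target if c in keep]
        reference = [c for c in reference if c in keep]
    return target, reference


def estimate_null_thresholds(
    expr: ExpressionMatrix,
    ann: ClusterAnnotation,
    cmp: Comparison,
    cfg: AnalysisConfig,
    rng: np.random.Generator | None = None,
    cells: tuple[list[str], list[str]] | None = None,
) -> ThresholdSet:
    """Permutation-null significance bands for a comparison.

    In each of ``n_null_rounds`` rounds, ``n_null_genes`` genes are drawn
    without replacement and all their pairwise correlations over the
    comparison's cells (and the group1-group2 differential correlations) are
    pooled.  The positive/negative thresholds are the ``null_quantile`` and
    ``1 - null_quantile`` quantiles of the pooled null.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cells is not None:
        target, reference = cells
    else:
        target, reference = _maybe_capped_cells(ann, cmp, cfg, rng)
    if len(target) < 3 or len(reference) < 3:
        raise ValueError("both comparison groups need at least 3 cells")
    n_genes = expr.n_genes
    panel = min(cfg.n_null_genes, n_genes)
    if panel < cfg.n_null_genes:
        warnings.warn(
            f"only {n_genes} genes available; null panels use all of them",
            stacklevel=2,
        )
    t_idx = expr.cell_indices(target)
    r_idx = expr.cell_indices(reference)
    a_idx = np.concatenate([t_idx, r_idx])
    corr_pool: list[np.ndarray] = []
    diff_pool: list[np.ndarray] = []
    X = sp.csr_matrix(expr.values)
    iu = np.triu_indices(panel, k=1)
    for _ in range(cfg.n_null_rounds):
        genes = rng.choice(n_genes, size=panel, replace=False)
        sub_all = sp.csr_matrix(X[genes][:, a_idx])
        r_al = _pearson_from_sparse(sub_all, sub_all)[iu]
        sub_t = sp.csr_matrix(X[genes][:, t_idx])
        sub_r = sp.csr_matrix(X[genes][:, r_idx])
        r_t = _pearson_from_sparse(sub_t, sub_t)[iu]
        r_r = _pearson_from_sparse(sub_r, sub_r)[iu]
        corr_pool.append(r_al.astype(np.float32))
        diff_pool.append((r_t - r_r).astype(np.float32))
    corr = np.concatenate(corr_pool)
    diff = np.concatenate(diff_pool)
    corr = corr[np.isfinite(corr)]
    diff = diff[np.isfinite(diff)]
    q_hi, q_lo = cfg.null_quantile, 1 - cfg.null_quantile
    return ThresholdSet(
        corr_pos=float(max(np.quantile(corr, q_hi), 0.0)),
        corr_neg=float(min(np.quantile(corr, q_lo), 0.0)),
        diff_pos=float(max(np.quantile(diff, q_hi), 0.0)),
        diff_neg=float(min(np.quantile(diff, q_lo), 0.0)),
        comparison=cmp,
    )


def _edge_significant(
    r_all: np.ndarray, diff: np.ndarray, th: ThresholdSet
) -> np.ndarray:
    """Vectorised candidate rule; NaN statistics never fire a route."""
    with np.errstate(invalid="ignore"):
        sig = (
            (r_all > th.corr_pos)
            | (r_all < th.corr_neg)
            | (diff > th.diff_pos)
            | (diff < th.diff_neg)
        )
    return np.nan_to_num(sig, nan=False) if sig.dtype != bool else sig


def find_candidate_edges(
    expr: ExpressionMatrix,
    ann: ClusterAnnotation,
    cmp: Comparison,
    core: CoreGeneResult,
    th: ThresholdSet,
    cells: tuple[list[str], list[str]] | None = None,
) -> list[CoexpressionEdge]:
    """Core-gene x all-gene pairs passing either correlation route.

    A pair is a candidate when its overall correlation exceeds the positive
    or negative band, or its differential correlation (target minus
    reference) exceeds the differential bands.
    """
    if not core.core_genes:
        raise ValueError("no core genes to seed the network")
    if cells is None:
        target, reference = comparison_cells(ann, cmp)
    else:
        target, reference = cells
    t_idx = expr.cell_indices(target)
    r_idx = expr.cell_indices(reference)
    a_idx = np.concatenate([t_idx, r_idx])
    core_idx = expr.gene_indices(core.core_genes)
    r_all = sparse_pearson(expr, core_idx, np.arange(expr.n_genes), a_idx)
    r_g1 = sparse_pearson(expr, core_idx, np.arange(expr.n_genes), t_idx)
    r_g2 = sparse_pearson(expr, core_idx, np.arange(expr.n_genes), r_idx)
    diff = r_g1 - r_g2
    sig = _edge_significant(r_all, diff, th)
    edges: list[CoexpressionEdge] = []
    for i, cg in enumerate(core.core_genes):
        for j in np.flatnonzero(sig[i]):
            if expr.gene_ids[j] == cg:
                continue
            edges.append(
                CoexpressionEdge(
                    core=cg,
                    secondary=expr.gene_ids[j],
                    r_all=float(r_all[i, j]),
                    r_group1=float(r_g1[i, j]),
                    r_group2=float(r_g2[i, j]),
                    diff_corr=float(diff[i, j]),
                )
            )
    return edges


def _stratified_fraction(
    cluster_of: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a ``frac`` subsample preserving each cluster's share."""
    keep: list[np.ndarray] = []
    for cl in np.unique(cluster_of):
        idx = np.flatnonzero(cluster_of == cl)
        n = max(1, int(round(frac * idx.size)))
        keep.append(rng.choice(idx, size=n, replace=False))
    return np.concatenate(keep)


def bootstrap_edges(
    expr: ExpressionMatrix,
    ann: ClusterAnnotation,
    cmp: Comparison,
    candidates: list[CoexpressionEdge],
    th: ThresholdSet,
    cfg: AnalysisConfig,
    rng: np.random.Generator | None = None,
    cells: tuple[list[str], list[str]] | None = None,
) -> CoexpressionNetwork:
    """Retain candidate edges that stay significant in > K of n_boot subsamples.

    Each round draws a ``boot_frac`` subsample of the comparison's cells
    without replacement, stratified by cluster so the cluster distribution is
    preserved, and re-applies the candidate rule with the same thresholds.
    """
    if not candidates:
        return CoexpressionNetwork(cmp, [])
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cells is None:
        target, reference = comparison_cells(ann, cmp)
    else:
        target, reference = cells
    all_cells = target + reference
    cell_idx = expr.cell_indices(all_cells)
    n_target = len(target)
    cluster_of = np.array([ann.labels[c] for c in all_cells])

    cores = sorted({e.core for e in candidates})
    secs = sorted({e.secondary for e in candidates})
    core_pos = {g: i for i, g in enumerate(cores)}
    sec_pos = {g: j for j, g in enumerate(secs)}
    pair_i = np.array([core_pos[e.core] for e in candidates])
    pair_j = np.array([sec_pos[e.secondary] for e in candidates])

    X = sp.csr_matrix(expr.values[:, cell_idx])
    core_rows = sp.csr_matrix(X[expr.gene_indices(cores)])
    sec_rows = sp.csr_matrix(X[expr.gene_indices(secs)])

    support = np.zeros(len(candidates), dtype=int)
    for _ in range(cfg.n_boot):
        keep = _stratified_fraction(cluster_of, cfg.boot_frac, rng)
        in_t = keep[keep < n_target]
        in_r = keep[keep >= n_target]
        if in_t.size < 3 or in_r.size < 3:
            continue
        r_all = _pearson_from_sparse(core_rows[:, keep], sec_rows[:, keep])
        r_t = _pearson_from_sparse(core_rows[:, in_t], sec_rows[:, in_t])
        r_r = _pearson_from_sparse(core_rows[:, in_r], sec_rows[:, in_r])
        sig = _edge_significant(r_all, r_t - r_r, th)
        support += sig[pair_i, pair_j]

    edges = []
    for e, s in zip(candidates, support):
        if s > cfg.K:
            edges.append(
                CoexpressionEdge(
                    e.core, e.secondary, e.r_all, e.r_group1, e.r_group2,
                    e.diff_corr, support=int(s),
                )
            )
    return CoexpressionNetwork(cmp, edges)
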