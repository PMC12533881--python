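"""Marker-gene ranking and filtering.

Stable core-secondary pairs are scored with the *adjusted differential
correlation*: the product of the pair's pathway count and its strongest
correlation magnitude (``diffmet``), each normalised by the comparison-wide
maximum.  Genes appearing in pairs above 20% of the maximal score are then
filtered on differential expression (|log2FC| >= 0.5) and on the fraction of
target-cluster cells expressing them (>= 0.45).  Surviving genes are the
comparison's markers, annotated with the pathways whose members they are most
correlated with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .coexpression import CoexpressionEdge, CoexpressionNetwork, ThresholdSet, sparse_pearson
from .config import AnalysisConfig, Comparison
from .core_selection import comparison_cells
from .io import ClusterAnnotation, ExpressionMatrix, PathwayCollection

__all__ = [
    "ScoredPair",
    "MarkerGene",
    "diffmet",
    "adjusted_differential",
    "select_markers",
    "log2_fold_change",
    "fraction_expressing",
    "annotate_marker_pathways",
    "compare_correlation_distributions",
]


@dataclass
class ScoredPair:
    core: str
    secondary: str
    path_count: int
    diffmet: float
    adj_diff: float = 0.0


@dataclass
class MarkerGene:
    gene: str
    comparison: Comparison
    log2fc: float
    frac_expressing: float
    origin: str  # "core" | "secondary" | "both"
    pathway_annotations: list[tuple[str, int]] = field(default_factory=list)


def diffmet(edge: CoexpressionEdge, signed: bool = False) -> float:
    """Strongest correlation signal of a pair.

    The maximum magnitude among the overall correlation, the two within-group
    correlations and the differential correlation.  Absolute values are used
    by default so that strong negative co-expression scores as strongly as
    positive co-expression; ``signed=True`` takes the max of the raw values
    instead.  NaN statistics contribute zero.
    """
    vals = np.array([edge.r_all, edge.r_group1, edge.r_group2, edge.diff_corr])
    vals = np.nan_to_num(vals, nan=0.0)
    return float(np.max(vals) if signed else np.max(np.abs(vals)))


def adjusted_differential(
    edges: list[CoexpressionEdge],
    pair_counts: dict[tuple[str, str], int],
    cfg: AnalysisConfig | None = None,
) -> list[ScoredPair]:
    """Score pairs by (path_ij / max path) * (diffmet_ij / max diffmet)."""
    cfg = cfg or AnalysisConfig()
    if not edges:
        return []
    pairs = [
        ScoredPair(
            core=e.core,
            secondary=e.secondary,
            path_count=pair_counts.get((e.core, e.secondary), 0),
            diffmet=diffmet(e, signed=cfg.diffmet_signed),
        )
        for e in edges
    ]
    max_path = max(p.path_count for p in pairs)
    max_dm = max(p.diffmet for p in pairs)
    if max_path == 0 or max_dm == 0:
        warnings.warn(
            "no pathway (or correlation) signal among pairs; all adjusted "
            "differential scores are zero",
            stacklevel=2,
        )
        return pairs
    for p in pairs:
        p.adj_diff = (p.path_count / max_path) * (p.diffmet / max_dm)
    return pairs


def log2_fold_change(
    expr: ExpressionMatrix,
    gene_idx: np.ndarray,
    target_cols: np.ndarray,
    reference_cols: np.ndarray,
) -> np.ndarray:
    """Average-expression log2 fold change on the natural (de-logged) scale.

    log2[(mean(expm1 x) + 1)_target / (mean(expm1 x) + 1)_reference], the
    conventional single-cell definition; the +1 pseudocount keeps it finite.
    """
    X = expr.values[gene_idx]
    t = X[:, target_cols].copy()
    r = X[:, reference_cols].copy()
    t.data = np.expm1(t.data)
    r.data = np.expm1(r.data)
    mean_t = np.asarray(t.sum(axis=1)).ravel() / t.shape[1]
    mean_r = np.asarray(r.sum(axis=1)).ravel() / r.shape[1]
    return np.log2((mean_t + 1.0) / (mean_r + 1.0))


def fraction_expressing(
    expr: ExpressionMatrix, gene_idx: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    X = expr.values[gene_idx][:, cols]
    return np.asarray((X > 0).sum(axis=1)).ravel() / cols.size


def select_markers(
    pairs: list[ScoredPair],
    expr: ExpressionMatrix,
    ann: ClusterAnnotation,
    cmp: Comparison,
    cfg: AnalysisConfig,
    core_genes: list[str] | None = None,
    cells: tuple[list[str], list[str]] | None = None,
) -> list[MarkerGene]:
    """Filter genes of high-scoring pairs on fold change and expression fraction."""
    if expr.scale != "lognorm":
        raise ValueError("marker selection requires lognorm-scale expression")
    if not pairs:
        return []
    max_adj = max(p.adj_diff for p in pairs)
    qualified = [p for p in pairs if p.adj_diff > cfg.adj_frac * max_adj]
    core_set = set(core_genes) if core_genes is not None else {p.core for p in pairs}
    as_core: set[str] = set()
    as_secondary: set[str] = set()
    for p in qualified:
        as_core.add(p.core)
        as_secondary.add(p.secondary)
    candidates = sorted(as_core | as_secondary)
    if not candidates:
        return []
    if cells is None:
        target, reference = comparison_cells(ann, cmp)
    else:
        target, reference = cells
    t_cols = expr.cell_indices(target)
    r_cols = expr.cell_indices(reference)
    gene_idx = expr.gene_indices(candidates)
    fc = log2_fold_change(expr, gene_idx, t_cols, r_cols)
    frac_t = fraction_expressing(expr, gene_idx, t_cols)
    if cfg.frac_expr_mode == "max":
        frac_r = fraction_expressing(expr, gene_idx, r_cols)
        frac = np.maximum(frac_t, frac_r)
    else:
        frac = frac_t
    markers: list[MarkerGene] = []
    for g, f, fr, fr_t in zip(candidates, fc, frac, frac_t):
        if abs(f) < cfg.fc_cut or fr < cfg.frac_expr_cut:
            continue
        if g in core_set:
            origin = "both" if g in as_secondary else "core"
        else:
            origin = "secondary"
        markers.append(
            MarkerGene(
                gene=g,
                comparison=cmp,
                log2fc=float(f),
                frac_expressing=float(fr_t),
                origin=origin,
            )
        )
    return markers


def annotate_marker_pathways(
    marker: str,
    expr: ExpressionMatrix,
    ann: ClusterAnnotation,
    cmp: Comparison,
    pathways: PathwayCollection,
    th: ThresholdSet,
    cells: tuple[list[str], list[str]] | None = None,
) -> list[tuple[str, int]]:
    """Rank pathways by how many member genes are significantly correlated
    with the marker over the comparison's cells.

    Significance uses the comparison's null correlation bands.  Ties are
    broken by descending mean |r| over the counted genes, then by name.
    """
    if cells is None:
        target, reference = comparison_cells(ann, cmp)
    else:
        target, reference = cells
    cols = np.concatenate(
        [expr.cell_indices(target), expr.cell_indices(reference)]
    )
    r = sparse_pearson(expr, [marker], np.arange(expr.n_genes), cols).ravel()
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    scored: list[tuple[str, int, float]] = []
    for name in pathways.names():
        members = [g for g in pathways.genes(name) if g in gene_pos and g != marker]
        if not members:
            continue
        rs = np.array([r[gene_pos[g]] for g in members])
        with np.errstate(invalid="ignore"):
            sig = (rs > th.corr_pos) | (rs < th.corr_neg)
        count = int(np.nansum(sig))
        if count == 0:
            continue
        mean_abs = float(np.mean(np.abs(rs[sig])))
        scored.append((name, count, mean_abs))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(name, count) for name, count, _ in scored]


def compare_correlation_distributions(
    corrs_group1: np.ndarray,
    corrs_group2: np.ndarray,
    rng: np.random.Generator | None = None,
    min_values: int = 100,
) -> tuple[float, float]:
    """Two-sample KS test between two sets of correlation values.

    Groups with fewer than ``min_values`` entries are resampled with
    replacement up to exactly ``min_values`` first, so small pathways still
    yield a comparable test.  Returns (KS statistic, p-value) under the null
    that both samples come from the same distribution.
    """
    a = np.asarray(corrs_group1, dtype=float)
    b = np.asarray(corrs_group2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        # identical samples (as multisets): no resampling noise, D = 0
        return 0.0, 1.0
    rng = rng if rng is not None else np.random.default_rng(0)
    if a.size < min_values:
        a = rng.choice(a, size=min_values, replace=True)
    if b.size < min_values:
        b = rng.choice(b, size=min_values, replace=True)
    stat, p = ks_2samp(a, b)
    return float(stat), float(p)
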