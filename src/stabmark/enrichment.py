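"""Over-representation analysis of core-gene modules against a pathway collection.

Each core gene together with its stable secondary genes forms a query set
that is tested pathway-by-pathway with the one-sided hypergeometric upper
tail, followed by Benjamini-Hochberg FDR control within the query.  The
per-pair pathway counts produced here (``path_ij``) feed the marker ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .coexpression import CoexpressionNetwork
from .config import AnalysisConfig
from .io import PathwayCollection

__all__ = ["EnrichmentResult", "ora", "enrich_core_modules", "expression_universe"]


@dataclass
class EnrichmentResult:
    core: str
    pathway: str
    overlap: int
    input_size: int
    pathway_size: int
    universe_size: int
    p_value: float
    fdr: float


def expression_universe(
    gene_ids: list[str], pathways: PathwayCollection
) -> frozenset[str]:
    """Background universe: expressed genes annotated to at least one pathway."""
    annotated = pathways.all_genes()
    return frozenset(g for g in gene_ids if g in annotated)


def ora(
    query: set[str] | frozenset[str],
    pathways: PathwayCollection,
    universe: set[str] | frozenset[str],
    fdr_cut: float = 0.05,
    core: str = "",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each pathway.

    p = P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|pathway|, n=|query|),
    BH-corrected across the pathways tested for this query; results with
    fdr <= ``fdr_cut`` are returned sorted by p-value.
    """
    if not universe:
        raise ValueError("empty universe")
    universe = frozenset(universe)
    query = frozenset(query) & universe
    if not query:
        return []
    N, n = len(universe), len(query)
    rows: list[EnrichmentResult] = []
    for name in pathways.names():
        genes = pathways.genes(name) & universe
        if not genes:
            continue
        K = len(genes)
        k = len(query & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentResult(core, name, k, n, K, N, min(p, 1.0), 1.0))
    if not rows:
        return []
    _, fdrs, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
    for r, q in zip(rows, fdrs):
        r.fdr = float(q)
    kept = [r for r in rows if r.fdr <= fdr_cut]
    kept.sort(key=lambda r: (r.p_value, r.pathway))
    return kept


def enrich_core_modules(
    net: CoexpressionNetwork,
    pathways: PathwayCollection,
    universe: set[str] | frozenset[str],
    cfg: AnalysisConfig | None = None,
) -> tuple[dict[str, list[EnrichmentResult]], dict[tuple[str, str], int]]:
    """ORA per core-gene module and per-pair pathway counts.

    For each core gene c, the query is {c} plus its stable secondaries.
    ``path_ij[(c, s)]`` counts c's significant pathways that contain the
    secondary s (default rule), or that contain both c and s when
    ``cfg.pair_pathway_rule == "both"``.
    """
    cfg = cfg or AnalysisConfig()
    results: dict[str, list[EnrichmentResult]] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for core in net.core_genes():
        secondaries = net.secondaries_of(core)
        query = {core, *secondaries}
        enr = ora(query, pathways, universe, fdr_cut=cfg.ora_fdr, core=core)
        results[core] = enr
        sig_sets = [pathways.genes(r.pathway) for r in enr]
        for s in secondaries:
            if cfg.pair_pathway_rule == "both":
                count = sum(1 for gs in sig_sets if s in gs and core in gs)
            else:
                count = sum(1 for gs in sig_sets if s in gs)
            pair_counts[(core, s)] = count
    return results, pair_counts
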