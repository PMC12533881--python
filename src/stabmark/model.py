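"""Model / results interface over the marker-selection pipeline.

:class:`MarkerAnalysis` is built from an expression matrix, cluster labels
and (optionally) a pathway collection; :meth:`MarkerAnalysis.fit` runs the
stage sequence — core-gene selection, null-threshold calibration, candidate
edges, bootstrap stabilisation, over-representation, marker ranking and
pathway scoring — for each requested cluster comparison and returns a
:class:`MarkerAnalysisResults` carrying the per-comparison artefacts and
tidy tables.  When a run directory is given, each completed stage is
checkpointed as a delimited table plus a JSON manifest so an interrupted
analysis resumes from the last finished step.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import (
    CoexpressionEdge,
    CoexpressionNetwork,
    ThresholdSet,
    bootstrap_edges,
    estimate_null_thresholds,
    find_candidate_edges,
    _maybe_capped_cells,
)
from .config import AnalysisConfig, Comparison
from .core_selection import CoreGeneResult, select_core_genes
from .enrichment import EnrichmentResult, enrich_core_modules, expression_universe
from .io import (
    ClusterAnnotation,
    ExpressionMatrix,
    PathwayCollection,
    log_normalize,
    read_expression,
    read_pathways_gmt,
)
from .markers import (
    MarkerGene,
    ScoredPair,
    adjusted_differential,
    annotate_marker_pathways,
    select_markers,
)
from .pathway_scoring import (
    PathwayScore,
    corr_express,
    pathway_significance,
    rank_pathways,
)

__all__ = ["MarkerAnalysis", "MarkerAnalysisResults", "ComparisonResult"]

@dataclass
class ComparisonResult:
    """Everything the pipeline produced for one cluster comparison."""

    comparison: Comparison
    core: CoreGeneResult
    thresholds: ThresholdSet
    network: CoexpressionNetwork
    enrichment: dict[str, list[EnrichmentResult]]
    pair_counts: dict[tuple[str, str], int]
    scored_pairs: list[ScoredPair]
    markers: list[MarkerGene]
    pathway_scores: list[PathwayScore]


class MarkerAnalysisResults:
    """Results container with tidy tables and a text summary."""

    def __init__(
        self,
        model: "MarkerAnalysis",
        per_comparison: dict[str, ComparisonResult],
    ) -> None:
        self.model = model
        self.per_comparison = per_comparison

    def __getitem__(self, label: str) -> ComparisonResult:
        return self.per_comparison[label]

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for label, res in self.per_comparison.items():
            for m in res.markers:
                rows.append(
                    {
                        "comparison": label,
                        "gene": m.gene,
                        "log2fc": m.log2fc,
                        "frac_expressing": m.frac_expressing,
                        "origin": m.origin,
                        "pathways": ";".join(
                            f"{p}:{c}" for p, c in m.pathway_annotations[:5]
                        ),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "comparison", "gene", "log2fc", "frac_expressing", "origin",
                "pathways",
            ],
        )

    def pathway_table(self) -> pd.DataFrame:
        rows = []
        for label, res in self.per_comparison.items():
            for rank, s in enumerate(res.pathway_scores, start=1):
                rows.append(
                    {
                        "comparison": label,
                        "pathway": s.pathway,
                        "pos_corr_express": s.pos_corr_express,
                        "neg_corr_express": s.neg_corr_express,
                        "final_measure": s.final_measure,
                        "n_pairs_enriched": s.n_pairs_enriched,
                        "p_expression": s.p_expression,
                        "p_coexpression": s.p_coexpression,
                        "rank": rank,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "comparison", "pathway", "pos_corr_express", "neg_corr_express",
                "final_measure", "n_pairs_enriched", "p_expression",
                "p_coexpression", "rank",
            ],
        )

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for label, res in self.per_comparison.items():
            for e in res.network.edges:
                rows.append(
                    {
                        "comparison": label, "core": e.core,
                        "secondary": e.secondary, "r_all": e.r_all,
                        "r_group1": e.r_group1, "r_group2": e.r_group2,
                        "diff_corr": e.diff_corr, "support": e.support,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "comparison", "core", "secondary", "r_all", "r_group1",
                "r_group2", "diff_corr", "support",
            ],
        )

    def summary(self) -> str:
        lines = [
            "Stabilized marker analysis",
            "=" * 60,
            f"genes: {self.model.expr.n_genes}   cells: {self.model.expr.n_cells}"
            f"   clusters: {len(self.model.clusters.clusters)}",
            "",
            f"{'comparison':<24}{'core':>6}{'edges':>7}{'markers':>9}"
            f"{'sec-only':>10}{'pathways':>10}",
            "-" * 66,
        ]
        for label, res in self.per_comparison.items():
            sec = sum(1 for m in res.markers if m.origin == "secondary")
            lines.append(
                f"{label:<24}{len(res.core.core_genes):>6}"
                f"{len(res.network.edges):>7}{len(res.markers):>9}"
                f"{sec:>10}{len(res.pathway_scores):>10}"
            )
        return "\n".join(lines)


class MarkerAnalysis:
    """Marker-gene and pathway selection model for a clustered expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Gene x cell matrix; raw counts are log-normalised on construction.
    clusters : ClusterAnnotation
        Cluster label per cell; every cell of ``expr`` must be labelled.
    pathways : PathwayCollection, optional
        Gene sets for enrichment; without them pathway-dependent scores are
        zero and markers carry no annotations.
    config : AnalysisConfig, optional
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        clusters: ClusterAnnotation,
        pathways: PathwayCollection | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        self.config = config or AnalysisConfig()
        if expr.scale == "counts":
            expr = log_normalize(expr, self.config.scale_factor)
        self.expr = expr
        clusters.validate_against(expr)
        self.clusters = clusters
        self.pathways = pathways

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        clusters_path: str | Path,
        gmt_path: str | Path | None = None,
        config: AnalysisConfig | None = None,
    ) -> "MarkerAnalysis":
        expr = read_expression(expression_path)
        ann = ClusterAnnotation.from_table(clusters_path)
        pw = read_pathways_gmt(gmt_path) if gmt_path else None
        return cls(expr, ann, pw, config)

    def default_comparisons(self) -> list[Comparison]:
        return [
            Comparison("one_vs_all", target=cl)
            for cl in self.clusters.clusters
        ]

    # ------------------------------------------------------------------
    def fit(
        self,
        comparisons: list[Comparison] | None = None,
        run_dir: str | Path | None = None,
        force: bool = False,
        verbose: bool = False,
    ) -> MarkerAnalysisResults:
        comparisons = comparisons or self.default_comparisons()
        ckpt = _Checkpoints(Path(run_dir), self.config, force) if run_dir else None
        results: dict[str, ComparisonResult] = {}
        for k, cmp in enumerate(comparisons):
            results[cmp.label] = self._fit_one(cmp, k, ckpt, verbose)
        if ckpt:
            ckpt.save_manifest()
        return MarkerAnalysisResults(self, results)

    def _fit_one(
        self,
        cmp: Comparison,
        k: int,
        ckpt: "_Checkpoints | None",
        verbose: bool,
    ) -> ComparisonResult:
        cfg = self.config
        expr, ann = self.expr, self.clusters

        def stage_rng(tag: int) -> np.random.Generator:
            return np.random.default_rng(np.random.SeedSequence([cfg.seed, k, tag]))

        def log(msg: str) -> None:
            if verbose:
                print(f"[{cmp.label}] {msg}", flush=True)

        t0 = time.time()
        # the per-cluster cell cap is fixed once per comparison and shared by
        # every correlation stage
        cells = _maybe_capped_cells(ann, cmp, cfg, stage_rng(0))

        # once any stage recomputes, every later stage must too: checkpoints
        # downstream of a fresh result are stale by construction
        dirty = False

        core = ckpt.load_core(cmp) if ckpt else None
        if core is None:
            core = select_core_genes(expr, ann, cmp, cfg)
            dirty = True
            if ckpt:
                ckpt.save_core(cmp, core)
        log(f"core genes: {len(core.core_genes)}"
            + (" (fallback)" if core.fallback_used else "")
            + f"  [{time.time() - t0:.1f}s]")

        th = ckpt.load_thresholds(cmp) if (ckpt and not dirty) else None
        if th is None:
            th = estimate_null_thresholds(
                expr, ann, cmp, cfg, rng=stage_rng(1), cells=cells
            )
            dirty = True
            if ckpt:
                ckpt.save_thresholds(cmp, th)
        log(f"thresholds: corr=({th.corr_neg:.3f},{th.corr_pos:.3f}) "
            f"diff=({th.diff_neg:.3f},{th.diff_pos:.3f})")

        net = ckpt.load_network(cmp) if (ckpt and not dirty) else None
        if net is None:
            candidates = find_candidate_edges(expr, ann, cmp, core, th, cells=cells)
            net = bootstrap_edges(
                expr, ann, cmp, candidates, th, cfg, rng=stage_rng(2), cells=cells
            )
            dirty = True
            if ckpt:
                ckpt.save_network(cmp, net)
        log(f"stable edges: {len(net.edges)}  [{time.time() - t0:.1f}s]")

        if self.pathways is not None and net.edges:
            loaded = ckpt.load_enrichment(cmp) if (ckpt and not dirty) else None
            if loaded is None:
                universe = expression_universe(expr.gene_ids, self.pathways)
                enr, pair_counts = enrich_core_modules(
                    net, self.pathways, universe, cfg
                )
                dirty = True
                if ckpt:
                    ckpt.save_enrichment(cmp, enr, pair_counts)
            else:
                enr, pair_counts = loaded
        else:
            enr, pair_counts = {}, {}

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = adjusted_differential(net.edges, pair_counts, cfg)
        markers = ckpt.load_markers(cmp) if (ckpt and not dirty) else None
        if markers is None:
            markers = select_markers(
                pairs, expr, ann, cmp, cfg,
                core_genes=core.core_genes, cells=cells,
            )
            if self.pathways is not None:
                for m in markers:
                    m.pathway_annotations = annotate_marker_pathways(
                        m.gene, expr, ann, cmp, self.pathways, th, cells=cells
                    )
            dirty = True
            if ckpt:
                ckpt.save_markers(cmp, markers)
        log(f"markers: {len(markers)}  [{time.time() - t0:.1f}s]")

        scores = ckpt.load_pathway_scores(cmp) if (ckpt and not dirty) else None
        if scores is None:
            scores = self._score_pathways(cmp, net, enr, cells, stage_rng(3))
            if ckpt:
                ckpt.save_pathway_scores(cmp, scores)
        log(f"pathways scored: {len(scores)}  [{time.time() - t0:.1f}s]")

        return ComparisonResult(
            cmp, core, th, net, enr, pair_counts, pairs, markers, scores
        )

    def _score_pathways(
        self,
        cmp: Comparison,
        net: CoexpressionNetwork,
        enr: dict[str, list[EnrichmentResult]],
        cells: tuple[list[str], list[str]],
        rng: np.random.Generator,
    ) -> list[PathwayScore]:
        if self.pathways is None:
            return []
        sig_pathways = sorted({r.pathway for results in enr.values() for r in results})
        scores: list[PathwayScore] = []
        gene_set = set(self.expr.gene_ids)
        for name in sig_pathways:
            members = sorted(self.pathways.genes(name) & gene_set)
            n_pairs = sum(
                1 for e in net.edges
                if e.core in members and e.secondary in members
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = corr_express(
                    name, members, self.expr, self.clusters, cmp,
                    n_pairs_enriched=n_pairs, cells=cells,
                )
            if s is None:
                continue
            s.p_expression, s.p_coexpression = pathway_significance(
                members, self.expr, self.clusters, cmp, rng,
                n_random=self.config.n_random_sets, cells=cells,
            )
            scores.append(s)
        return rank_pathways(scores)


# ---------------------------------------------------------------------------
# checkpointing


class _Checkpoints:
    """Stage persistence: delimited tables plus a JSON manifest."""

    def __init__(self, run_dir: Path, cfg: AnalysisConfig, force: bool) -> None:
        self.dir = run_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.force = force
        self.manifest_path = self.dir / "manifest.json"
        if self.manifest_path.exists() and not force:
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"config": asdict(cfg), "stages": {}}

    def _path(self, cmp: Comparison, stage: str, ext: str = "tsv") -> Path:
        return self.dir / f"{stage}_{cmp.label}.{ext}"

    def _usable(self, path: Path) -> bool:
        return path.exists() and not self.force

    def _mark(self, cmp: Comparison, stage: str, path: Path) -> None:
        self.manifest["stages"][f"{stage}:{cmp.label}"] = {
            "status": "done", "path": path.name,
        }
        self.save_manifest()

    def save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2) + "\n")

    # core ---------------------------------------------------------------
    def save_core(self, cmp: Comparison, core: CoreGeneResult) -> None:
        path = self._path(cmp, "core")
        df = pd.DataFrame(
            {
                "gene_id": list(core.selection_counts),
                "selection_count": list(core.selection_counts.values()),
            }
        )
        df["is_core"] = df["gene_id"].isin(core.core_genes)
        df.to_csv(path, sep="\t", index=False)
        self.manifest["stages"][f"core:{cmp.label}"] = {
            "status": "done", "path": path.name,
            "fallback_used": core.fallback_used,
        }
        self.save_manifest()

    def load_core(self, cmp: Comparison) -> CoreGeneResult | None:
        path = self._path(cmp, "core")
        if not self._usable(path):
            return None
        df = pd.read_csv(path, sep="\t")
        entry = self.manifest["stages"].get(f"core:{cmp.label}", {})
        return CoreGeneResult(
            cmp,
            dict(zip(df["gene_id"], df["selection_count"].astype(int))),
            sorted(df.loc[df["is_core"], "gene_id"].tolist()),
            bool(entry.get("fallback_used", False)),
        )

    # thresholds ---------------------------------------------------------
    def save_thresholds(self, cmp: Comparison, th: ThresholdSet) -> None:
        path = self._path(cmp, "thresholds", "json")
        path.write_text(json.dumps({
            "corr_pos": th.corr_pos, "corr_neg": th.corr_neg,
            "diff_pos": th.diff_pos, "diff_neg": th.diff_neg,
        }, indent=2) + "\n")
        self._mark(cmp, "thresholds", path)

    def load_thresholds(self, cmp: Comparison) -> ThresholdSet | None:
        path = self._path(cmp, "thresholds", "json")
        if not self._usable(path):
            return None
        d = json.loads(path.read_text())
        return ThresholdSet(comparison=cmp, **d)

    # network ------------------------------------------------------------
    def save_network(self, cmp: Comparison, net: CoexpressionNetwork) -> None:
        path = self._path(cmp, "network")
        pd.DataFrame(
            [
                {
                    "core": e.core, "secondary": e.secondary, "r_all": e.r_all,
                    "r_group1": e.r_group1, "r_group2": e.r_group2,
                    "diff_corr": e.diff_corr, "support": e.support,
                }
                for e in net.edges
            ],
            columns=[
                "core", "secondary", "r_all", "r_group1", "r_group2",
                "diff_corr", "support",
            ],
        ).to_csv(path, sep="\t", index=False)
        self._mark(cmp, "network", path)

    def load_network(self, cmp: Comparison) -> CoexpressionNetwork | None:
        path = self._path(cmp, "network")
        if not self._usable(path):
            return None
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        edges = [
            CoexpressionEdge(
                str(r.core), str(r.secondary), float(r.r_all),
                float(r.r_group1), float(r.r_group2), float(r.diff_corr),
                int(r.support),
            )
            for r in df.itertuples()
        ]
        return CoexpressionNetwork(cmp, edges)

    # enrichment ---------------------------------------------------------
    def save_enrichment(
        self,
        cmp: Comparison,
        enr: dict[str, list[EnrichmentResult]],
        pair_counts: dict[tuple[str, str], int],
    ) -> None:
        path = self._path(cmp, "enrichment")
        rows = [
            {
                "core": r.core, "pathway": r.pathway, "overlap": r.overlap,
                "input_size": r.input_size, "pathway_size": r.pathway_size,
                "universe_size": r.universe_size, "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for results in enr.values()
            for r in results
        ]
        pd.DataFrame(
            rows,
            columns=[
                "core", "pathway", "overlap", "input_size", "pathway_size",
                "universe_size", "p_value", "fdr",
            ],
        ).to_csv(path, sep="\t", index=False)
        ppath = self._path(cmp, "paircounts")
        pd.DataFrame(
            [
                {"core": c, "secondary": s, "n_pathways": n}
                for (c, s), n in pair_counts.items()
            ],
            columns=["core", "secondary", "n_pathways"],
        ).to_csv(ppath, sep="\t", index=False)
        self._mark(cmp, "enrichment", path)

    def load_enrichment(
        self, cmp: Comparison
    ) -> tuple[dict[str, list[EnrichmentResult]], dict[tuple[str, str], int]] | None:
        path = self._path(cmp, "enrichment")
        ppath = self._path(cmp, "paircounts")
        if not (self._usable(path) and ppath.exists()):
            return None
        df = pd.read_csv(path, sep="\t")
        enr: dict[str, list[EnrichmentResult]] = {}
        for r in df.itertuples():
            enr.setdefault(str(r.core), []).append(
                EnrichmentResult(
                    str(r.core), str(r.pathway), int(r.overlap),
                    int(r.input_size), int(r.pathway_size),
                    int(r.universe_size), float(r.p_value), float(r.fdr),
                )
            )
        pdf = pd.read_csv(ppath, sep="\t")
        pair_counts = {
            (str(r.core), str(r.secondary)): int(r.n_pathways)
            for r in pdf.itertuples()
        }
        return enr, pair_counts

    # markers ------------------------------------------------------------
    def save_markers(self, cmp: Comparison, markers: list[MarkerGene]) -> None:
        path = self._path(cmp, "markers")
        pd.DataFrame(
            [
                {
                    "gene": m.gene, "log2fc": m.log2fc,
                    "frac_expressing": m.frac_expressing, "origin": m.origin,
                    "pathways": ";".join(
                        f"{p}:{c}" for p, c in m.pathway_annotations
                    ),
                }
                for m in markers
            ],
            columns=["gene", "log2fc", "frac_expressing", "origin", "pathways"],
        ).to_csv(path, sep="\t", index=False)
        self._mark(cmp, "markers", path)

    def load_markers(self, cmp: Comparison) -> list[MarkerGene] | None:
        path = self._path(cmp, "markers")
        if not self._usable(path):
            return None
        df = pd.read_csv(path, sep="\t", keep_default_na=False,
                         float_precision="round_trip")
        markers = []
        for r in df.itertuples():
            annot = []
            if r.pathways:
                for item in str(r.pathways).split(";"):
                    name, _, count = item.rpartition(":")
                    annot.append((name, int(count)))
            markers.append(
                MarkerGene(
                    str(r.gene), cmp, float(r.log2fc),
                    float(r.frac_expressing), str(r.origin), annot,
                )
            )
        return markers

    # pathway scores -----------------------------------------------------
    def save_pathway_scores(
        self, cmp: Comparison, scores: list[PathwayScore]
    ) -> None:
        path = self._path(cmp, "pathways")
        pd.DataFrame(
            [
                {
                    "pathway": s.pathway,
                    "pos_corr_express": s.pos_corr_express,
                    "neg_corr_express": s.neg_corr_express,
                    "final_measure": s.final_measure,
                    "n_pairs_enriched": s.n_pairs_enriched,
                    "p_expression": s.p_expression,
                    "p_coexpression": s.p_coexpression,
                }
                for s in scores
            ],
            columns=[
                "pathway", "pos_corr_express", "neg_corr_express",
                "final_measure", "n_pairs_enriched", "p_expression",
                "p_coexpression",
            ],
        ).to_csv(path, sep="\t", index=False)
        self._mark(cmp, "pathways", path)

    def load_pathway_scores(self, cmp: Comparison) -> list[PathwayScore] | None:
        path = self._path(cmp, "pathways")
        if not self._usable(path):
            return None
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return [
            PathwayScore(
                str(r.pathway), float(r.pos_corr_express),
                float(r.neg_corr_express), float(r.final_measure),
                int(r.n_pairs_enriched), float(r.p_expression),
                float(r.p_coexpression),
            )
            for r in df.itertuples()
        ]
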