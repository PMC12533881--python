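"""Synthetic pathway-structured expression data and the selection benchmark.

The generator emulates the role a large reference single-cell matrix plays in
the simulation design: a gene pool (default 2,000 genes) organised into
overlapping pathways whose members share latent cell factors, so that within-
pathway co-expression is real and controllable.  A subset of highly connected
pathway genes receives large phenotype effects (beta ~ Unif([-10,-5] U
[5,10])); all remaining genes receive negligible effects (Unif([-0.1, 0.1])).
Phenotypes follow a linear (X beta) or nonlinear (plus pairwise interactions
among the predictive genes) model, Gaussian noise scaled to a target
signal-to-noise proportion is added, and binary labels are drawn through a
logistic transformation.  The benchmark runs marker-selection methods over a
parameter grid and reports gene- and pathway-level recovery (F1/TPR/FDR)
plus cross-dataset stability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import ranksums

from .coexpression import sparse_pearson
from .config import AnalysisConfig, Comparison
from .enrichment import expression_universe, ora
from .io import ClusterAnnotation, ExpressionMatrix, PathwayCollection, log_normalize
from .model import MarkerAnalysis

__all__ = [
    "SimulationConfig",
    "SimulationGrid",
    "SimulatedDataset",
    "Metrics",
    "StabilityReport",
    "generate_pathway_db",
    "generate_base_expression",
    "select_predictive_genes",
    "simulate_phenotype",
    "simulate_dataset",
    "evaluate",
    "stability_measure",
    "wilcoxon_marker_genes",
    "run_benchmark",
]

TRUTH_BETA_LOW, TRUTH_BETA_HIGH = 5.0, 10.0
NULL_BETA = 0.1
LOGISTIC_SCALE = 5.0  # slope applied to the standardised signal before sigmoid


@dataclass
class SimulationConfig:
    """One cell of the simulation design grid."""

    n_pathways_core: int = 5          # p: pathways carrying predictive genes
    n_predictive_genes: int = 10      # n: genes with large effects
    snr: float = 0.9                  # proportion of signal variance
    model: str = "linear"             # or "nonlinear"
    n_genes_total: int = 2000
    n_cells: int = 500
    n_pathways_db: int = 40           # total pathways in the synthetic collection
    pathway_size_range: tuple[int, int] = (20, 40)
    overlap_frac: float = 0.2
    module_strength: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("linear", "nonlinear"):
            raise ValueError(f"unknown phenotype model {self.model!r}")
        if not (0 < self.snr < 1):
            raise ValueError("snr must lie in (0, 1)")
        if self.n_predictive_genes > self.n_genes_total:
            raise ValueError("more predictive genes than genes")


@dataclass
class SimulationGrid:
    """The printed factorial design: p x n x snr x model x reps."""

    p_values: tuple[int, ...] = (5, 10, 15)
    n_values: tuple[int, ...] = (10, 20, 30, 40)
    snr_values: tuple[float, ...] = (0.7, 0.8, 0.9)
    models: tuple[str, ...] = ("linear", "nonlinear")
    n_reps: int = 50
    base: SimulationConfig = field(default_factory=SimulationConfig)

    def expand(self) -> list[tuple[SimulationConfig, int]]:
        """All (config, rep) cells of the grid; the default design has 3,600."""
        out = []
        for p, n, snr, model, rep in itertools.product(
            self.p_values, self.n_values, self.snr_values, self.models,
            range(self.n_reps),
        ):
            cfg = SimulationConfig(
                n_pathways_core=p, n_predictive_genes=n, snr=snr, model=model,
                n_genes_total=self.base.n_genes_total,
                n_cells=self.base.n_cells,
                n_pathways_db=self.base.n_pathways_db,
                pathway_size_range=self.base.pathway_size_range,
                overlap_frac=self.base.overlap_frac,
                module_strength=self.base.module_strength,
                seed=self.base.seed,
            )
            out.append((cfg, rep))
        return out


@dataclass
class SimulatedDataset:
    expr: ExpressionMatrix          # lognorm scale
    labels: ClusterAnnotation       # clusters "case" / "control"
    truth_genes: frozenset[str]
    truth_pathways: frozenset[str]
    betas: dict[str, float]
    pathway_db: PathwayCollection


@dataclass
class Metrics:
    tp: int
    fp: int
    fn: int
    f1: float
    tpr: float
    fdr: float


@dataclass
class StabilityReport:
    S: float
    per_cluster_pairwise: dict[tuple[str, str, str], float]


# ---------------------------------------------------------------------------
# generators


def generate_pathway_db(
    n_pathways: int,
    size_range: tuple[int, int],
    overlap_frac: float,
    n_genes_total: int,
    rng: np.random.Generator,
) -> PathwayCollection:
    """Pathways over a global gene pool with controlled pairwise sharing.

    Each pathway after the first draws round(overlap_frac * size) members
    from genes already used by earlier pathways and the remainder from the
    untouched pool, so ``overlap_frac = 0`` gives pairwise-disjoint sets.
    Genes are named ``G0000``..; pool exhaustion raises an error.
    """
    lo, hi = size_range
    if lo < 5:
        raise ValueError("pathway sizes must be >= 5")
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must lie in [0, 1)")
    width = max(4, len(str(n_genes_total - 1)))
    gene_pool = [f"G{i:0{width}d}" for i in range(n_genes_total)]
    unused = list(gene_pool)
    used: list[str] = []
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = int(round(overlap_frac * size)) if used else 0
        n_shared = min(n_shared, len(used))
        n_fresh = size - n_shared
        if n_fresh > len(unused):
            raise ValueError(
                f"gene pool exhausted at pathway {k}: need {n_fresh} fresh "
                f"genes, {len(unused)} left"
            )
        shared = (
            [used[i] for i in rng.choice(len(used), size=n_shared, replace=False)]
            if n_shared else []
        )
        fresh_idx = rng.choice(len(unused), size=n_fresh, replace=False)
        fresh = [unused[i] for i in sorted(fresh_idx, reverse=True)]
        for i in sorted(fresh_idx, reverse=True):
            unused.pop(i)
        used.extend(fresh)
        members = frozenset(shared) | frozenset(fresh)
        pathways[f"PW{k:03d}"] = (f"synthetic pathway {k}", members)
    return PathwayCollection(pathways)


def generate_base_expression(
    pathway_db: PathwayCollection,
    n_cells: int,
    n_genes_total: int = 2000,
    module_strength: float = 0.6,
    rng: np.random.Generator | None = None,
    mean_log_expression: float = np.log(1.5),
    mean_sd: float = 0.6,
    scale: str = "lognorm",
) -> ExpressionMatrix:
    """Latent-factor count generator with within-pathway co-expression.

    Every pathway owns a standard-normal latent factor per cell; a member
    gene's latent value mixes its pathways' factors (weight
    sqrt(module_strength)) with independent noise.  Latent values modulate a
    per-gene lognormal base rate and Poisson counts are drawn, giving sparse,
    over-dispersed count-like data; the default output is the log-normalised
    matrix ready for correlation work (``scale="counts"`` returns raw counts).
    """
    if not (0 <= module_strength < 1):
        raise ValueError("module_strength must lie in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    width = max(4, len(str(n_genes_total - 1)))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes_total)]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    names = pathway_db.names()
    factors = rng.standard_normal((len(names), n_cells))
    membership: list[list[int]] = [[] for _ in gene_ids]
    for k, name in enumerate(names):
        for g in pathway_db.genes(name):
            if g in gene_pos:
                membership[gene_pos[g]].append(k)
    a = np.sqrt(module_strength)
    b = np.sqrt(1.0 - module_strength)
    z = rng.standard_normal((n_genes_total, n_cells)) * 1.0
    for gi, mem in enumerate(membership):
        if mem:
            shared = factors[mem].sum(axis=0) / np.sqrt(len(mem))
            z[gi] = a * shared + b * z[gi]
    base = rng.lognormal(mean=mean_log_expression, sigma=mean_sd, size=n_genes_total)
    s = 0.7  # latent-to-rate slope; keeps biological variance comparable to noise
    rate = base[:, None] * np.exp(s * z - 0.5 * s * s)
    counts = rng.poisson(rate).astype(np.float64)
    mat = ExpressionMatrix(sp.csr_matrix(counts), gene_ids,
                           [f"C{j:05d}" for j in range(n_cells)], scale="counts")
    if scale == "counts":
        return mat
    return log_normalize(mat)


def select_predictive_genes(
    expr: ExpressionMatrix,
    pathway_db: PathwayCollection,
    p: int,
    n: int,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Choose p pathways and their n most connected, most shared genes.

    Gene score = (normalised sum of |r| to the other genes of the selected
    pathways) * (1 + normalised count of selected pathways the gene belongs
    to), favouring genes that are both highly co-expressed and shared across
    pathways.
    """
    names = pathway_db.names()
    if p > len(names):
        raise ValueError("p exceeds the number of pathways")
    chosen = [names[i] for i in rng.choice(len(names), size=p, replace=False)]
    pool = sorted(
        set().union(*(pathway_db.genes(nm) for nm in chosen)) & set(expr.gene_ids)
    )
    if len(pool) < n:
        raise ValueError(f"selected pathways contain only {len(pool)} genes (< {n})")
    r = sparse_pearson(expr, pool, pool)
    np.fill_diagonal(r, np.nan)
    conn = np.nansum(np.abs(r), axis=1)
    conn_norm = conn / conn.max() if conn.max() > 0 else conn
    counts = np.array(
        [sum(1 for nm in chosen if g in pathway_db.genes(nm)) for g in pool],
        dtype=float,
    )
    score = conn_norm * (1.0 + counts / counts.max())
    order = sorted(range(len(pool)), key=lambda i: (-score[i], pool[i]))
    return [pool[i] for i in order[:n]], chosen


def simulate_phenotype(
    expr: ExpressionMatrix,
    truth_genes: list[str],
    model: str,
    snr: float,
    rng: np.random.Generator,
    binarize: str = "bernoulli",
    sign_groups: dict[str, int] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Binary phenotype from gene effects, target SNR noise and a logistic link.

    Effects for truth genes are drawn from Unif([-10,-5] U [5,10]); all other
    genes get Unif([-0.1, 0.1]).  When ``sign_groups`` maps truth genes to
    co-regulation groups (e.g. their pathway), one fair sign is drawn per
    group and shared by its members — co-expressed effect genes then push the
    phenotype in a common direction instead of cancelling within a module;
    magnitudes stay per-gene.  The signal is X'beta on standardised lognorm
    expression; the nonlinear model adds standardised pairwise products of
    the truth genes with effects from the truth range.  Gaussian noise with
    variance Var(signal) * (1 - snr) / snr is added; labels are Bernoulli
    draws from sigmoid(LOGISTIC_SCALE * standardised noisy signal) (or a
    hard threshold at probability 0.5 with ``binarize="threshold"``).
    """
    if not (0 < snr < 1):
        raise ValueError("snr must lie in (0, 1)")
    truth = list(truth_genes)
    truth_set = set(truth)
    n_cells = expr.n_cells
    X = np.asarray(expr.values.todense())
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    group_signs: dict[int, float] = {}
    if sign_groups is not None:
        for grp in sorted({sign_groups[g] for g in truth if g in sign_groups}):
            group_signs[grp] = 1.0 if rng.random() < 0.5 else -1.0

    betas: dict[str, float] = {}
    signal = np.zeros(n_cells)
    for gi, g in enumerate(expr.gene_ids):
        if g in truth_set:
            mag = rng.uniform(TRUTH_BETA_LOW, TRUTH_BETA_HIGH)
            if sign_groups is not None and g in sign_groups:
                beta = group_signs[sign_groups[g]] * mag
            else:
                beta = mag if rng.random() < 0.5 else -mag
        else:
            beta = rng.uniform(-NULL_BETA, NULL_BETA)
        betas[g] = float(beta)
        signal += beta * Xs[gi]

    if model == "nonlinear":
        t_idx = expr.gene_indices(truth)
        for a in range(len(truth)):
            for b in range(a + 1, len(truth)):
                prod = Xs[t_idx[a]] * Xs[t_idx[b]]
                psd = prod.std()
                if psd == 0:
                    continue
                prod = (prod - prod.mean()) / psd
                mag = rng.uniform(TRUTH_BETA_LOW, TRUTH_BETA_HIGH)
                signal += (mag if rng.random() < 0.5 else -mag) * prod

    var_sig = signal.var()
    if var_sig == 0:
        raise ValueError("phenotype signal is constant")
    noise = rng.normal(0.0, np.sqrt(var_sig * (1.0 - snr) / snr), size=n_cells)
    noisy = signal + noise
    zscores = (noisy - noisy.mean()) / noisy.std()
    probs = 1.0 / (1.0 + np.exp(-LOGISTIC_SCALE * zscores))
    if binarize == "threshold":
        labels = (probs >= 0.5).astype(int)
    else:
        labels = (rng.random(n_cells) < probs).astype(int)
    return labels, betas


def simulate_dataset(cfg: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate one complete dataset from a simulation configuration."""
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    db = generate_pathway_db(
        cfg.n_pathways_db, cfg.pathway_size_range, cfg.overlap_frac,
        cfg.n_genes_total, rng,
    )
    expr = generate_base_expression(
        db, cfg.n_cells, cfg.n_genes_total, cfg.module_strength, rng
    )
    truth_genes, truth_pathways = select_predictive_genes(
        expr, db, cfg.n_pathways_core, cfg.n_predictive_genes, rng
    )
    labels, betas = simulate_phenotype(expr, truth_genes, cfg.model, cfg.snr, rng)
    # guard against a degenerate draw leaving one class nearly empty
    if min(labels.sum(), len(labels) - labels.sum()) < 25:
        flip = np.flatnonzero(labels == (0 if labels.sum() > len(labels) / 2 else 1))
        need = 25 - int(min(labels.sum(), len(labels) - labels.sum()))
        labels = labels.copy()
        labels[rng.choice(flip, size=need, replace=False)] ^= 1
    ann = ClusterAnnotation(
        labels={
            c: ("case" if y else "control")
            for c, y in zip(expr.cell_ids, labels)
        }
    )
    return SimulatedDataset(
        expr=expr,
        labels=ann,
        truth_genes=frozenset(truth_genes),
        truth_pathways=frozenset(truth_pathways),
        betas=betas,
        pathway_db=db,
    )


# ---------------------------------------------------------------------------
# evaluation


def evaluate(predicted: set[str] | frozenset[str], truth: set[str] | frozenset[str]) -> Metrics:
    """Set-comparison metrics; F1 = TP / (TP + 0.5 (FP + FN))."""
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    denom = tp + 0.5 * (fp + fn)
    f1 = tp / denom if denom > 0 else 0.0
    tpr = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    fdr = fp / (tp + fp) if (tp + fp) > 0 else 0.0
    return Metrics(tp, fp, fn, f1, tpr, fdr)


def stability_measure(
    marker_sets: dict[tuple[str, str], set[str]]
) -> StabilityReport:
    """Average pairwise percentage overlap of marker sets across datasets.

    ``marker_sets`` maps (dataset, cluster) -> marker gene set.  For every
    cluster shared by two datasets, (S_c)_ij = 100 |A n B| / min(|A|, |B|);
    the overall S is the mean of all pairwise values.  Pairs with an empty
    set are skipped with a warning.
    """
    import warnings as _w

    by_cluster: dict[str, list[tuple[str, set[str]]]] = {}
    for (ds, cl), genes in marker_sets.items():
        by_cluster.setdefault(cl, []).append((ds, set(genes)))
    pairwise: dict[tuple[str, str, str], float] = {}
    for cl, entries in by_cluster.items():
        entries.sort(key=lambda e: e[0])
        for (di, a), (dj, b) in itertools.combinations(entries, 2):
            if not a or not b:
                _w.warn(
                    f"empty marker set for cluster {cl!r} "
                    f"({di if not a else dj}); pair skipped",
                    stacklevel=2,
                )
                continue
            pairwise[(cl, di, dj)] = 100.0 * len(a & b) / min(len(a), len(b))
    if not pairwise:
        raise ValueError("no comparable dataset pairs")
    return StabilityReport(
        S=float(np.mean(list(pairwise.values()))),
        per_cluster_pairwise=pairwise,
    )


def reduced_benchmark_grid(
    n_reps: int = 5, n_cells: int = 500
) -> SimulationGrid:
    """Desk-scale benchmark design: p=5, n in {10,20}, snr in {0.8,0.9},
    both phenotype models, 5 repetitions (40 pipeline runs)."""
    return SimulationGrid(
        p_values=(5,), n_values=(10, 20), snr_values=(0.8, 0.9),
        models=("linear", "nonlinear"), n_reps=n_reps,
        base=SimulationConfig(n_cells=n_cells),
    )


def scaled_analysis_config(seed: int = 0) -> AnalysisConfig:
    """Pipeline configuration used for benchmark runs.

    Iteration counts that define the selection rules (200 LASSO iterations
    with theta=160, 100 bootstraps with K=80) are kept at their defaults;
    the null-threshold calibration uses 300-gene panels over 25 rounds and
    the penalty grid 3 values, which keeps a single run well under a minute
    without changing the calibrated quantiles appreciably.
    """
    return AnalysisConfig(
        seed=seed, n_null_genes=300, n_null_rounds=25, n_lambda=3
    )


# ---------------------------------------------------------------------------
# comparator plug-in and benchmark harness


def wilcoxon_marker_genes(
    expr: ExpressionMatrix,
    ann: ClusterAnnotation,
    target: str = "case",
    alpha: float = 0.05,
    fc_cut: float = 0.5,
) -> set[str]:
    """Reference comparator: per-gene rank-sum test with BH-FDR and |log2FC| filter."""
    from statsmodels.stats.multitest import multipletests

    from .markers import log2_fold_change

    t_cols = expr.cell_indices(ann.cells_of(target))
    r_cols = expr.cell_indices(ann.cells_not_of(target))
    X = np.asarray(expr.values.todense())
    pvals = np.ones(expr.n_genes)
    for gi in range(expr.n_genes):
        a, b = X[gi, t_cols], X[gi, r_cols]
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            continue
        pvals[gi] = ranksums(a, b).pvalue
    rej, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    fc = log2_fold_change(expr, np.arange(expr.n_genes), t_cols, r_cols)
    keep = rej & (np.abs(fc) >= fc_cut)
    return {expr.gene_ids[i] for i in np.flatnonzero(keep)}


def _pipeline_method(
    ds: SimulatedDataset, cfg: AnalysisConfig
) -> tuple[set[str], dict[str, int]]:
    """Run the full pipeline on a simulated dataset.

    Returns the marker gene set and a tally of marker origins
    (core / secondary / both).
    """
    model = MarkerAnalysis(ds.expr, ds.labels, ds.pathway_db, cfg)
    cmp = Comparison("one_vs_one", target="case", reference="control")
    res = model.fit(comparisons=[cmp])
    markers = res[cmp.label].markers
    origins = {"core": 0, "secondary": 0, "both": 0}
    for m in markers:
        origins[m.origin] += 1
    return {m.gene for m in markers}, origins


def run_benchmark(
    grid: SimulationGrid,
    analysis_config: AnalysisConfig | None = None,
    methods: dict | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> pd.DataFrame:
    """Run marker selection over the simulation grid.

    ``methods`` maps method name -> callable (SimulatedDataset) -> gene set;
    the pipeline itself is always included as method ``"pipeline"``.  Each
    row of the returned table holds one (grid cell, rep, method, level) with
    tp/fp/fn/f1/tpr/fdr; gene-level rows for the pipeline also carry marker
    origin counts.  Pathway-level predictions are the pathways over-
    represented (FDR <= 0.05) in the method's gene set.
    """
    analysis_config = analysis_config or AnalysisConfig()
    methods = dict(methods or {})
    rows: list[dict] = []
    cells = grid.expand()
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(len(cells)) % (2**31 - 1)
    for idx, ((sim_cfg, rep), run_seed) in enumerate(zip(cells, run_seeds)):
        ds = simulate_dataset(sim_cfg, seed=int(run_seed))
        universe = expression_universe(ds.expr.gene_ids, ds.pathway_db)
        acfg = AnalysisConfig(
            **{**analysis_config.__dict__, "seed": int(run_seed)}
        )
        preds: dict[str, tuple[set[str], dict[str, int] | None]] = {}
        pipeline_genes, origins = _pipeline_method(ds, acfg)
        pipeline_gm = evaluate(pipeline_genes, ds.truth_genes)
        preds["pipeline"] = (pipeline_genes, origins)
        for name, fn in methods.items():
            preds[name] = (set(fn(ds)), None)
        for name, (genes, orig) in preds.items():
            gm = evaluate(genes, ds.truth_genes)
            enriched = {
                r.pathway
                for r in ora(genes, ds.pathway_db, universe, fdr_cut=0.05)
            } if genes else set()
            pm = evaluate(enriched, ds.truth_pathways)
            base = {
                "p": sim_cfg.n_pathways_core,
                "n": sim_cfg.n_predictive_genes,
                "snr": sim_cfg.snr,
                "model": sim_cfg.model,
                "rep": rep,
                "method": name,
                "n_predicted": len(genes),
            }
            grow = {
                **base, "level": "gene",
                "tp": gm.tp, "fp": gm.fp, "fn": gm.fn,
                "f1": gm.f1, "tpr": gm.tpr, "fdr": gm.fdr,
            }
            if orig is not None:
                total = sum(orig.values())
                grow.update(
                    n_core_origin=orig["core"],
                    n_secondary_origin=orig["secondary"],
                    n_both_origin=orig["both"],
                    pct_secondary_only=(
                        100.0 * orig["secondary"] / total if total else np.nan
                    ),
                )
            rows.append(grow)
            rows.append(
                {
                    **base, "level": "pathway",
                    "tp": pm.tp, "fp": pm.fp, "fn": pm.fn,
                    "f1": pm.f1, "tpr": pm.tpr, "fdr": pm.fdr,
                }
            )
        if verbose:
            print(
                f"[{idx + 1}/{len(cells)}] p={sim_cfg.n_pathways_core} "
                f"n={sim_cfg.n_predictive_genes} snr={sim_cfg.snr} "
                f"{sim_cfg.model} rep={rep}: "
                f"F1={pipeline_gm.f1:.2f} FP={pipeline_gm.fp}",
                flush=True,
            )
    return pd.DataFrame(rows)
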