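# Methods

This note documents the statistical procedure implemented in `stabmark`,
the choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Model and procedure

The input is a gene × cell expression matrix with a cluster label per cell
and, optionally, a pathway collection (GMT). All correlation, fold-change
and pathway computations run on log-normalised values
(`log(1 + 10,000 · count / cell total)`); raw counts are transformed on
model construction. Analyses are per *comparison*: one cluster against all
remaining cells ("one vs all") or against a single other cluster
("one vs one"). An optional per-cluster cell cap (`max_cells_per_cluster`)
equalises cluster sizes before every regression and correlation stage,
because both are sensitive to severe class imbalance; the cap is resampled
per LASSO iteration but fixed once per comparison for the correlation
stages so that thresholds, edges and marker statistics describe the same
cell set.

### Core-gene selection

Per iteration (default `n_lasso_iter = 200`): split the comparison's cells
70/30, stratified by original cluster so both halves keep the cluster
composition; fit an L1-penalised binary logistic regression (target = 1) on
the sparse training matrix; record genes with non-zero coefficients. Genes
selected in strictly more than `theta = 160` iterations are core genes; if
none qualifies, the five most frequently selected genes are used and the
result flagged as a fallback (rank ties broken lexicographically).

The penalty strength is chosen per iteration on a log-spaced grid of
inverse-regularisation values (default 10 points on [0.03, 3]) by held-out
deviance on the iteration's 30% split, using the **one-standard-error
rule**: the sparsest value whose deviance is within one SE of the best.
The deviance argmin systematically prefers dense fits (over a hundred
non-zero coefficients) in which every gene correlated with the signal is
selected in nearly every iteration; that erases the distinction between
the regression route and the co-expression route that the method is built
on. The 1-SE rule is the standard sparse-selection compromise (glmnet's
`lambda.1se`). Genes expressed in none of the comparison's cells are
excluded from the design matrix and keep a selection count of zero.

### Co-expression network

Pearson correlations are computed from sparse cross-products
(r = (E[xy] − E[x]E[y]) / σxσy) without densifying the matrix; zero-variance
genes yield NaN, which never satisfies a significance rule. Null bands are
calibrated per comparison: `n_null_rounds = 100` panels of
`n_null_genes = 1000` random genes (sampled without replacement within a
panel), pooling all pairwise correlations over the comparison's cells and,
separately, the within-target minus within-reference differential
correlations. The positive/negative thresholds are the 97.5th and 2.5th
percentiles of the pooled null (one pooled null, both tails — not
per-sign one-sided nulls). The null pool is stored in float32: ~10⁸ values
at the default panel size, where quantile error from precision is
negligible next to Monte-Carlo error.

A (core, other) pair is a candidate edge when r_all or Δr = r₁ − r₂ falls
outside its band. Candidates are re-tested in `n_boot = 100` rounds on 60%
subsamples drawn **without replacement**, stratified by cluster (the
procedure subsamples rather than resamples: a with-replacement draw would
change the effective number of distinct cells entering each correlation);
edges significant in strictly more than `K = 80` rounds are retained.

### Enrichment, marker ranking, pathway scores

Each core gene with its stable secondaries forms a query for one-sided
hypergeometric over-representation against the pathway collection, with
BH-FDR within the query (per-module testing, not pooled across cores) at
0.05. The background universe is the set of expressed genes annotated to at
least one pathway — an expression-aware background avoids inflating
enrichment with genes the experiment could never have reported.
`path_ij` for a pair (core i, secondary j) counts i's significant pathways
containing j; requiring *both* genes to be members is available via
`pair_pathway_rule="both"`.

`diffmet_ij` is the maximum **absolute** value of {r_all, r₁, r₂, Δr}. The
signed maximum (available as `diffmet_signed=True`) would score a pair with
r = −0.9 below one with r = 0.1, discarding exactly the strong negative
co-expression the network analysis is meant to surface; the absolute form
is the default. Adjusted differential scores normalise by the
comparison-wide maxima, so the arg-max pair of both components scores 1.
Genes of pairs above `adj_frac = 0.20` of the maximal score are candidate
markers; the final filters are |log2FC| ≥ 0.5 — with
log2FC = log2[(mean expm1(x) + 1)_target / (mean expm1(x) + 1)_reference],
the conventional single-cell average fold change — and fraction of
target-cluster cells with non-zero expression ≥ 0.45 (a max-over-groups
variant is available). The `adj_frac` cut can be relaxed in the
configuration when markers are scarce; relaxation is never automatic.
Marker origins are reported as `core`, `secondary` (co-expression route
only) or `both`.

Marker pathway annotation counts, per pathway, the member genes whose
correlation with the marker exceeds the comparison's bands, ranked by
count with ties broken by mean |r| then name. The accompanying two-group
correlation-distribution contrasts use a two-sample KS test; groups with
fewer than 100 values are resampled with replacement to 100 first, matching
the tool's network-plot convention.

Every pathway enriched for at least one core module receives CorrExpress
scores: the sign-split per-gene mean-expression differences (each sum
divided by the total number of pathway genes present, n_i) times the mean
absolute pairwise correlation difference over **all** present pairs (the
co-expression factor is shared by the positive and negative terms, exactly
as the formulas are written). The final measure is max(|pos|, |neg|) — the
two directions are alternatives, not addends, and the max preserves the
per-direction reading while giving a single ranking key. Pathways with
fewer than two present genes are skipped with a warning. Significance
contrasts the pathway's per-gene expression-difference and per-pair |Δr|
distributions with those of `n_random_sets = 1` size-matched random gene
sets via exact two-sample KS tests on the raw value sets; resampling tiny
samples up to 100 values here would fabricate sample size and destroy
type-I calibration (verified: ~100% null rejection with resampling, ≤5%
without), so it is deliberately not applied in this test.

## Synthetic data generator

The generator stands in for a large reference single-cell matrix. A pool of
2,000 genes is organised into ~40 pathways of 20–40 genes with a controlled
shared fraction (default 0.2 of each pathway's members drawn from earlier
pathways). Each pathway owns a standard-normal latent factor per cell; a
member gene's latent value is √m · (mean of its pathways' factors) +
√(1−m) · noise with `module_strength m = 0.6`, chosen so realized
within-module |r| ≈ 0.3–0.4 against a ≈ 0.04 background — the strength of a
clear but not artificial co-expression module. Latent values modulate
per-gene lognormal base rates (median 1.5) and Poisson counts are drawn,
giving over-dispersed, zero-containing count data (~35% zeros), which is
then log-normalised.

Predictive genes are the n most connected, most shared members of p
selected pathways (normalised Σ|r| within the selected pathways times
1 + normalised membership count). Their effects are drawn from
Unif([−10,−5] ∪ [5,10]); all remaining genes get Unif([−0.1, 0.1]). The
phenotype signal is X'β on standardised expression; the nonlinear model
adds standardised pairwise products of the predictive genes with effects
from the same range. SNR is defined as the proportion of signal variance,
Var(signal)/(Var(signal)+Var(noise)), so Gaussian noise with variance
Var(signal)(1−snr)/snr hits the target exactly. Binary labels are Bernoulli
draws from sigmoid(5 · standardised noisy signal); the slope 5 keeps the
Bayes error low so that the binary labels preserve the "mostly signal"
regime the 0.7–0.9 SNR grid describes (at shallow slopes the label noise,
not the SNR, dominates and most planted genes fall below the method's own
fold-change filter). Hard thresholding at probability 0.5 is available.

What the generator does **not** emulate: empirical library-size variation,
dropout beyond Poisson sampling, batch effects, heavy-tailed dispersion,
and cluster structure richer than the binary phenotype. Passing benchmarks
therefore demonstrate correct mechanics and sensible behaviour under
controlled co-expression and effect sizes — not performance on real tissue.

## Benchmark and problem sizes

The full published design (p ∈ {5,10,15} × n ∈ {10,20,30,40} ×
SNR ∈ {0.7,0.8,0.9} × {linear, nonlinear} × 50 repetitions) enumerates
3,600 runs and is available through `SimulationGrid`. The package's
routine benchmark is the desk-scale subset p = 5, n ∈ {10, 20},
SNR ∈ {0.8, 0.9}, both models, 5 repetitions (40 runs) at 500 cells ×
2,000 genes, with the analysis configured at 300-gene null panels over 25
rounds and a 3-point penalty grid; the selection rules themselves (200
LASSO iterations, θ = 160, 100 bootstraps, K = 80) are never scaled. Gene-
level predictions are the emitted markers; pathway-level predictions are
the pathways over-represented in the predicted gene set (FDR ≤ 0.05). A
rank-sum comparator (BH-FDR + |log2FC| filter) is included as a reference
plug-in; re-implementations of MAST/DESeq2/ROC/Bimod are out of scope —
external methods plug in as `(dataset) → gene set` callables.

Non-predictive genes carry small non-zero effects (|β| ≤ 0.1) but are
scored as negatives, so reported false-positive counts are conservative.

## Numerical and reproducibility notes

- All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning (per comparison and stage), so identical configurations
  reproduce identical tables bit-for-bit.
- Correlations are clipped to [−1, 1] to absorb floating-point excess;
  degenerate (zero-variance) genes propagate NaN and are treated as
  "not significant" wherever a rule is evaluated, and contribute 0 to
  `diffmet`.
- Stage checkpoints are delimited tables plus a JSON manifest; floats are
  parsed back with round-trip precision so resumed results equal fresh
  ones exactly. Deleting a checkpoint invalidates everything downstream of
  it; completed stages upstream are never recomputed unless forced.
- Stability S uses min(|A|,|B|) as the pairwise denominator: for equal-size
  top-N lists it reduces to the percentage of shared genes out of N, and it
  extends to variable-size marker sets without penalising the larger set.

## Known limitations

- The LASSO stage fits each penalty value from scratch per iteration;
  a warm-started coordinate-descent path would be faster for large grids.
- Null-threshold pools are Monte-Carlo estimates; at the scaled settings
  (300 genes × 25 rounds) the 97.5th-percentile SE is ≈ 2–3% relative.
- `one_vs_one` comparisons for many clusters grow quadratically; only
  one-vs-all comparisons are generated by default.
- Gene identifiers are matched to pathway collections by exact string
  equality; species or symbol mapping must happen upstream.
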