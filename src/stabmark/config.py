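"""Analysis configuration and cluster-comparison descriptors."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

ALL = "ALL"


@dataclass(frozen=True)
class Comparison:
    """A binary contrast: one cluster against another or against all the rest."""

    mode: str  # "one_vs_all" | "one_vs_one"
    target: str
    reference: str = ALL

    def __post_init__(self) -> None:
        if self.mode not in ("one_vs_all", "one_vs_one"):
            raise ValueError(f"unknown comparison mode {self.mode!r}")
        if self.mode == "one_vs_all" and self.reference != ALL:
            raise ValueError("one_vs_all comparisons use reference=ALL")
        if self.mode == "one_vs_one" and self.reference == ALL:
            raise ValueError("one_vs_one comparisons need an explicit reference")
        if self.target == self.reference:
            raise ValueError("target and reference must differ")

    @property
    def label(self) -> str:
        ref = "all" if self.reference == ALL else self.reference
        return f"{self.target}_vs_{ref}"


@dataclass
class AnalysisConfig:
    """Tunable parameters of the marker-selection pipeline.

    The defaults mirror the method's published operating point: 200 penalised
    logistic-regression iterations with a core-gene threshold of 160 (80%),
    70/30 train/test splits, null correlation thresholds from 1000 random
    genes over 100 rounds at the 97.5th percentile, 100 bootstrap rounds on
    60% stratified subsamples with edge retention above K=80, over-
    representation at FDR 0.05, a 20%-of-max adjusted-differential cut, and
    marker filters |log2FC| >= 0.5 and fraction-expressing >= 0.45.
    """

    n_lasso_iter: int = 200
    theta: int = 160
    train_frac: float = 0.70
    n_null_genes: int = 1000
    n_null_rounds: int = 100
    null_quantile: float = 0.975
    n_boot: int = 100
    boot_frac: float = 0.60
    K: int = 80
    ora_fdr: float = 0.05
    adj_frac: float = 0.20
    fc_cut: float = 0.5
    frac_expr_cut: float = 0.45
    max_cells_per_cluster: int | None = None
    seed: int = 0
    # --- secondary knobs (conventional choices, see docs/methods.md) ---
    scale_factor: float = 1e4          # library-size target for log-normalisation
    n_lambda: int = 10                 # size of the per-iteration L1 strength grid
    lambda_min: float = 3e-2           # smallest inverse-regularisation C on the grid
    lambda_max: float = 3.0            # largest C on the grid
    min_target_cells: int = 20         # smallest admissible target cluster
    pair_pathway_rule: str = "secondary"   # or "both": membership rule for path_ij
    diffmet_signed: bool = False       # True reproduces a signed max variant
    frac_expr_mode: str = "target"     # or "max": group used for fraction expressing
    n_random_sets: int = 1             # random gene sets per pathway significance test
    fallback_size: int = 5             # core genes kept when none clears theta

    def __post_init__(self) -> None:
        if not (0 < self.theta <= self.n_lasso_iter):
            raise ValueError("theta must satisfy 0 < theta <= n_lasso_iter")
        if not (0 < self.K <= self.n_boot):
            raise ValueError("K must satisfy 0 < K <= n_boot")
        for name in ("train_frac", "boot_frac", "adj_frac", "frac_expr_cut"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0.5 < self.null_quantile < 1):
            raise ValueError("null_quantile must lie in (0.5, 1)")
        if self.pair_pathway_rule not in ("secondary", "both"):
            raise ValueError("pair_pathway_rule must be 'secondary' or 'both'")
        if self.frac_expr_mode not in ("target", "max"):
            raise ValueError("frac_expr_mode must be 'target' or 'max'")

    # --- (de)serialisation -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from JSON or flat ``key=value`` text."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for key, val in raw.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(val, str):
                if val.lower() in ("true", "false"):
                    val = val.lower() == "true"
                elif val.lower() in ("none", ""):
                    val = None
                else:
                    try:
                        val = int(val)
                    except ValueError:
                        try:
                            val = float(val)
                        except ValueError:
                            pass
            kwargs[key] = val
        return cls(**kwargs)
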