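"""Data containers and I/O for expression matrices, cluster labels and gene sets.

The in-memory model is a sparse gene x cell matrix plus ordered identifier
lists.  Expression values are flagged as raw ``counts`` or ``lognorm``
(natural log of 1 + library-size-scaled counts); all correlation and
fold-change computations downstream operate on the lognorm scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "ClusterAnnotation",
    "PathwayCollection",
    "FormatError",
    "read_expression",
    "write_expression_mtx",
    "log_normalize",
    "read_pathways_gmt",
    "write_pathways_gmt",
    "balanced_subsample",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Sparse gene x cell expression matrix with identifiers and a scale flag.

    Parameters
    ----------
    values : scipy.sparse matrix, shape (n_genes, n_cells)
        Stored as CSR internally.
    gene_ids, cell_ids : sequence of str
        Ordered, unique identifiers for rows and columns.
    scale : {"counts", "lognorm"}
        Whether entries are raw counts or log1p library-normalised values.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.scale not in ("counts", "lognorm"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values.data)):
            raise FormatError("expression matrix contains non-finite entries")
        if self.scale == "counts" and self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def cell_indices(self, cells: Iterable[str]) -> np.ndarray:
        return np.array([self._cell_index[c] for c in cells], dtype=int)

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        idx = self.cell_indices(cells)
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.cell_ids[i] for i in idx],
            scale=self.scale,
        )


@dataclass
class ClusterAnnotation:
    """Per-cell cluster labels.

    ``labels`` maps cell id -> cluster name; ``clusters`` preserves first-seen
    order.  Every cluster must contain at least two cells.
    """

    labels: dict[str, str]
    clusters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clusters:
            seen: list[str] = []
            for c in self.labels.values():
                if c not in seen:
                    seen.append(c)
            self.clusters = seen
        counts = self.cluster_sizes()
        for cl in self.clusters:
            if counts.get(cl, 0) < 2:
                raise ValueError(f"cluster {cl!r} has fewer than 2 cells")

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def cells_of(self, cluster: str) -> list[str]:
        return [c for c, lab in self.labels.items() if lab == cluster]

    def cells_not_of(self, cluster: str) -> list[str]:
        return [c for c, lab in self.labels.items() if lab != cluster]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [c for c in expr.cell_ids if c not in self.labels]
        if missing:
            raise ValueError(
                f"{len(missing)} cells lack a cluster label (first: {missing[0]!r})"
            )

    @classmethod
    def from_table(cls, path: str | Path) -> "ClusterAnnotation":
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
        if df.shape[1] < 2:
            raise FormatError("cluster table needs (cell_id, cluster) columns")
        cells = df.iloc[:, 0].tolist()
        _check_unique(cells, "cell")
        labels = dict(zip(cells, df.iloc[:, 1].tolist()))
        return cls(labels=labels)

    def to_table(self, path: str | Path) -> None:
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(
            {"cell_id": list(self.labels), "cluster": list(self.labels.values())}
        ).to_csv(path, sep=sep, index=False)


@dataclass
class PathwayCollection:
    """Named gene sets (e.g. KEGG / GO pathways read from a GMT file)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def names(self) -> list[str]:
        return list(self.pathways)

    def genes(self, name: str) -> frozenset[str]:
        return self.pathways[name][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    def restricted_to(self, universe: Iterable[str]) -> "PathwayCollection":
        uni = frozenset(universe)
        kept = {
            name: (desc, genes & uni)
            for name, (desc, genes) in self.pathways.items()
            if genes & uni
        }
        return PathwayCollection(kept)

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, genes in self.pathways.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix.

    ``mtx_dir``: a directory with ``matrix.mtx`` plus one-column ``genes.tsv``
    (or ``features.tsv``) and ``barcodes.tsv`` (or ``cells.tsv``) files.
    ``delimited``: genes as rows, header row of cell ids; TSV/CSV picked by
    extension.  The scale defaults to counts unless a ``scale.txt`` sidecar
    (mtx_dir) declares ``lognorm``.
    """
    path = Path(path)
    if format is None:
        format = "mtx_dir" if path.is_dir() else "delimited"
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown expression format {format!r}")


def _find_first(path: Path, names: Sequence[str], what: str) -> Path:
    for n in names:
        p = path / n
        if p.exists():
            return p
    raise FormatError(f"no {what} file in {path} (looked for {', '.join(names)})")


def _read_id_file(p: Path) -> list[str]:
    # one id per line; extra tab-separated columns (10x style) are ignored
    out = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line.split("\t")[0])
    return out


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    mtx = _find_first(path, ["matrix.mtx"], "matrix-market")
    genes = _read_id_file(_find_first(path, ["genes.tsv", "features.tsv"], "gene id"))
    cells = _read_id_file(_find_first(path, ["barcodes.tsv", "cells.tsv"], "cell id"))
    mat = sp.csr_matrix(scipy.io.mmread(mtx))
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes / "
            f"{len(cells)} cells"
        )
    scale = "counts"
    sidecar = path / "scale.txt"
    if sidecar.exists() and sidecar.read_text().strip() == "lognorm":
        scale = "lognorm"
    return ExpressionMatrix(mat, genes, cells, scale=scale)


def _read_delimited(path: Path) -> ExpressionMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    header: list[str] | None = None
    genes: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if header is None:
                # header may or may not carry a leading corner label
                header = fields[1:] if fields[0] in ("", "gene", "gene_id") else fields[1:]
                n_cells = len(header)
                continue
            if len(fields) - 1 != n_cells:
                raise FormatError(
                    f"line {lineno}: expected {n_cells} values, got {len(fields) - 1}"
                )
            genes.append(fields[0])
            rows.append(np.array(fields[1:], dtype=float))
    if header is None:
        raise FormatError(f"{path} is empty")
    mat = sp.csr_matrix(np.vstack(rows) if rows else np.empty((0, len(header))))
    return ExpressionMatrix(mat, genes, header, scale="counts")


def write_expression_mtx(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write in the mtx-dir layout readable by :func:`read_expression`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(expr.values))
    (path / "genes.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(expr.cell_ids) + "\n")
    (path / "scale.txt").write_text(expr.scale + "\n")


def log_normalize(expr: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalise to ``scale_factor`` counts per cell, then log1p.

    Zeros stay zero, so the sparsity pattern is preserved.  A cell with zero
    total counts cannot be normalised and raises an error naming the cell.
    """
    if expr.scale != "counts":
        raise ValueError("log_normalize expects a counts-scale matrix")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    mat = sp.csc_matrix(expr.values)
    totals = np.asarray(mat.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {expr.cell_ids[zero[0]]!r} has zero total counts")
    mat = mat.multiply(scale_factor / totals[None, :]).tocsr()
    mat.data = np.log1p(mat.data)
    return ExpressionMatrix(mat, list(expr.gene_ids), list(expr.cell_ids), scale="lognorm")


def read_pathways_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: name TAB description TAB gene [TAB gene ...] per line."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT line needs >= 3 fields")
            name, desc = fields[0], fields[1]
            if name in pathways:
                raise FormatError(f"line {lineno}: duplicate pathway name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"line {lineno}: pathway {name!r} has no genes")
            pathways[name] = (desc, genes)
    return PathwayCollection(pathways)


def write_pathways_gmt(pw: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in pw.pathways.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def balanced_subsample(
    ann: ClusterAnnotation, cap: int, rng: np.random.Generator
) -> set[str]:
    """Cap every cluster at ``cap`` cells, sampled without replacement.

    Used before correlation and regression stages so that a dominant cluster
    does not swamp the statistics.  Deterministic for a given generator state.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    chosen: set[str] = set()
    for cluster in ann.clusters:
        cells = sorted(ann.cells_of(cluster))
        if len(cells) <= cap:
            chosen.update(cells)
        else:
            idx = rng.choice(len(cells), size=cap, replace=False)
            chosen.update(cells[i] for i in idx)
    return chosen
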