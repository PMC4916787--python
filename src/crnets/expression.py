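"""Expression matrix loading, ORF collapsing and pairwise co-expression.

The pipeline consumes an already-normalised genes x conditions matrix (the
reference study used RMA-normalised microarrays; normalisation itself is
upstream of this package).  Co-expression is the sample Pearson correlation
of two genes' expression profiles across all conditions.

Missing values are rejected rather than pairwise-deleted: pairwise deletion
would silently change which observations each correlation is computed over,
breaking determinism and comparability across pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of normalised expression values."""

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.condition_ids = list(self.condition_ids)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if self.n_conditions < 2:
            raise ValidationError("expression matrix needs at least 2 conditions")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValidationError("condition ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


@dataclass
class CoexpressionMatrix:
    """Symmetric genes x genes Pearson correlation matrix.

    Entries for zero-variance (constant) genes are NaN and the affected
    genes are listed in ``undefined_genes``.
    """

    r: np.ndarray
    gene_ids: list[str]
    undefined_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValidationError("co-expression matrix shape does not match gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def save(self, matrix_path, genes_path) -> None:
        """Persist losslessly: binary matrix + gene-order sidecar TSV."""
        np.save(matrix_path, self.r, allow_pickle=False)
        with open(genes_path, "w", encoding="utf-8") as fh:
            fh.write("gene\tdefined\n")
            undef = set(self.undefined_genes)
            for g in self.gene_ids:
                fh.write(f"{g}\t{int(g not in undef)}\n")

    @classmethod
    def load(cls, matrix_path, genes_path) -> "CoexpressionMatrix":
        r = np.load(matrix_path, allow_pickle=False)
        genes, undefined = [], []
        with open(genes_path, "r", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                g, flag = line.rstrip("\n").split("\t")
                genes.append(g)
                if flag == "0":
                    undefined.append(g)
        return cls(r=r, gene_ids=genes, undefined_genes=undefined)


def read_expression(path) -> ExpressionMatrix:
    """Read an expression TSV: first column gene/ORF id, rest numeric.

    Duplicate row ids are allowed at this stage; :func:`collapse_orfs`
    resolves them to unique gene ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need >= 2 condition columns, found {df.shape[1]}")
    try:
        # numpy's string->float conversion is correctly rounded, so a written
        # shortest-repr TSV round-trips bit-exactly
        values = df.to_numpy(dtype=str).astype(np.float64)
    except ValueError:
        for i, j in ((i, j) for i in range(df.shape[0]) for j in range(df.shape[1])):
            try:
                float(df.values[i, j])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell {df.values[i, j]!r} at gene "
                    f"{df.index[i]!r}, condition {df.columns[j]!r}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: missing/NaN cell at gene {df.index[i]!r}, condition {df.columns[j]!r}"
        )
    gene_ids = [str(g) for g in df.index]
    condition_ids = [str(c) for c in df.columns]
    return ExpressionMatrix(values=values, gene_ids=gene_ids, condition_ids=condition_ids)


def collapse_orfs(expr: ExpressionMatrix, orf_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse ORF-level rows to gene level by per-condition arithmetic mean.

    Rows whose id is absent from the mapping are dropped with a logged count.
    Output gene ids are unique and lexicographically sorted.
    """
    mapped_rows: dict[str, list[int]] = {}
    n_dropped = 0
    for i, orf in enumerate(expr.gene_ids):
        gene = orf_to_gene.get(orf)
        if gene is None:
            n_dropped += 1
            continue
        mapped_rows.setdefault(gene, []).append(i)
    if n_dropped:
        logger.warning("collapse_orfs: dropped %d rows absent from the ORF mapping", n_dropped)
    if not mapped_rows:
        raise ValidationError("collapse_orfs: no rows survive the ORF mapping")
    genes = sorted(mapped_rows)
    out = np.empty((len(genes), expr.n_conditions), dtype=np.float64)
    for gi, gene in enumerate(genes):
        rows = mapped_rows[gene]
        out[gi] = expr.values[rows[0]] if len(rows) == 1 else expr.values[rows].mean(axis=0)
    return ExpressionMatrix(values=out, gene_ids=genes, condition_ids=expr.condition_ids)


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and return (centered, row L2 norms); constant rows norm 0."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    return centered, norms


def compute_coexpression(expr: ExpressionMatrix, chunk_size: int | None = None) -> CoexpressionMatrix:
    """Pearson correlation for every unordered gene pair over all conditions.

    ``chunk_size`` streams row blocks for memory-limited machines.  The
    kernel is a per-row matrix-vector product either way, so the result is
    bit-identical for every chunk size (a blocked matrix-matrix product
    would change BLAS accumulation order with the block shape).
    Constant genes yield NaN rows/columns and are reported.
    """
    if len(set(expr.gene_ids)) != len(expr.gene_ids):
        raise ValidationError("gene ids must be unique (collapse ORFs first)")
    centered, norms = _standardize_rows(expr.values)
    n = expr.n_genes
    defined = norms > 0
    undefined_genes = [g for g, d in zip(expr.gene_ids, defined) if not d]
    if undefined_genes:
        logger.info("compute_coexpression: %d constant genes yield undefined r", len(undefined_genes))
    safe_norms = np.where(defined, norms, 1.0)
    z = centered / safe_norms[:, None]
    r = np.empty((n, n), dtype=np.float64)
    step = n if chunk_size is None else max(1, int(chunk_size))
    for start in range(0, n, step):
        for i in range(start, min(start + step, n)):
            r[i] = z @ z[i]
    np.clip(r, -1.0, 1.0, out=r)
    # compute once per unordered pair and mirror -> exact symmetry
    iu = np.triu_indices(n, 1)
    r[(iu[1], iu[0])] = r[iu]
    np.fill_diagonal(r, 1.0)
    if undefined_genes:
        r[~defined, :] = np.nan
        r[:, ~defined] = np.nan
    return CoexpressionMatrix(r=r, gene_ids=list(expr.gene_ids), undefined_genes=undefined_genes)
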