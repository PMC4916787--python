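"""Average co-expression r (ACEr), permutation significance and sensitivity.

ACEr of an edge set is the arithmetic mean of the pairwise Pearson
co-expression r over its unordered gene pairs, self-pairs excluded (their
correlation is 1 by construction and would bias the mean upward).  The
reference ACEr — the mean over ALL gene pairs of the expression matrix —
is the baseline any edge set is compared against.

Significance uses a seeded permutation null: each permuted set is the same
number of distinct non-self pairs drawn uniformly without replacement from
all gene pairs of the matrix, and the one-sided empirical p-value carries
the standard +1 correction, p = (1 + #{null >= observed}) / (n_perm + 1).

The sensitivity analysis re-estimates ACEr on randomly chosen condition
subsets (without replacement within a replicate) to check that an edge
set's co-expression is not driven by a few conditions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._pairs import Pair, canonicalize_pairs, n_choose_2
from .errors import ValidationError
from .expression import CoexpressionMatrix, ExpressionMatrix, _standardize_rows

logger = logging.getLogger(__name__)


@dataclass
class ACErResult:
    """Mean pairwise co-expression of an edge set."""

    acer: float
    n_pairs_used: int
    n_pairs_skipped: int
    edge_set_label: str = "edge_set"
    p_value: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.acer <= 1.0:
            raise ValidationError(f"ACEr {self.acer} outside [-1, 1]")

    def to_json(self) -> str:
        payload = {
            "label": self.edge_set_label,
            "acer": self.acer,
            "n_pairs_used": self.n_pairs_used,
            "n_pairs_skipped": self.n_pairs_skipped,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class SensitivityDistribution:
    """Replicate ACEr values from condition subsampling."""

    replicate_acers: np.ndarray
    n_conditions: int
    n_replicates: int
    seed: int
    edge_set_label: str = "edge_set"

    def __post_init__(self) -> None:
        self.replicate_acers = np.asarray(self.replicate_acers, dtype=np.float64)
        if len(self.replicate_acers) != self.n_replicates:
            raise ValidationError("replicate count does not match n_replicates")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_acers))

    @property
    def std(self) -> float:
        return float(np.std(self.replicate_acers, ddof=1)) if self.n_replicates > 1 else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("acer\n")
            for v in self.replicate_acers:
                fh.write(f"{v!r}\n")


def _sorted_pairs(pairs: Iterable[tuple[str, str]]) -> list[Pair]:
    """Canonical, deduplicated, lexicographically sorted pair list.

    Sorting makes the extraction (hence summation) order deterministic and,
    for matrices whose gene ids are sorted, identical to upper-triangle
    enumeration order — so acer(all pairs) == reference_acer exactly.
    """
    return sorted(canonicalize_pairs(pairs))


def acer(pairs: Iterable[tuple[str, str]], coexpr: CoexpressionMatrix,
         label: str = "edge_set") -> ACErResult:
    """ACEr of an edge set against a co-expression matrix.

    Self-pairs raise; pairs with a gene missing from the matrix or with
    undefined co-expression are skipped and counted.
    """
    plist = _sorted_pairs(pairs)
    if not plist:
        raise ValidationError("empty pair set")
    gidx = coexpr.gene_index()
    ii, jj = [], []
    n_skipped = 0
    for g1, g2 in plist:
        i, j = gidx.get(g1), gidx.get(g2)
        if i is None or j is None:
            n_skipped += 1
        else:
            ii.append(i)
            jj.append(j)
    vals = coexpr.r[np.asarray(ii, dtype=np.intp), np.asarray(jj, dtype=np.intp)] \
        if ii else np.empty(0)
    defined = ~np.isnan(vals)
    n_skipped += int((~defined).sum())
    used = vals[defined]
    if used.size == 0:
        raise ValidationError(f"{label}: no usable pairs (all missing or undefined)")
    return ACErResult(
        acer=float(np.mean(used)),
        n_pairs_used=int(used.size),
        n_pairs_skipped=n_skipped,
        edge_set_label=label,
    )


def reference_acer(coexpr: CoexpressionMatrix, label: str = "reference") -> ACErResult:
    """ACEr over all C(N,2) distinct gene pairs of the matrix."""
    n = coexpr.n_genes
    if n < 2:
        raise ValidationError("reference ACEr needs >= 2 genes")
    vals = coexpr.r[np.triu_indices(n, 1)]
    defined = ~np.isnan(vals)
    used = vals[defined]
    if used.size == 0:
        raise ValidationError("no defined gene pairs in the co-expression matrix")
    return ACErResult(
        acer=float(np.mean(used)),
        n_pairs_used=int(used.size),
        n_pairs_skipped=int((~defined).sum()),
        edge_set_label=label,
    )


def acer_permutation_test(pairs: Iterable[tuple[str, str]], coexpr: CoexpressionMatrix,
                          n_perm: int = 999, seed: int = 0,
                          label: str = "edge_set") -> float:
    """One-sided empirical p-value of an edge set's ACEr.

    Null sets are |pairs| distinct non-self pairs drawn uniformly without
    replacement from all gene pairs of the matrix; p is in
    [1/(n_perm+1), 1] by the +1 correction.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = acer(pairs, coexpr, label=label).acer
    m = len(canonicalize_pairs(pairs))
    total = n_choose_2(coexpr.n_genes)
    if m > total:
        raise ValidationError(f"{m} pairs exceed the {total} available gene pairs")
    r_cond = coexpr.r[np.triu_indices(coexpr.n_genes, 1)]
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        idx = rng.choice(total, size=m, replace=False)
        vals = r_cond[idx]
        vals = vals[~np.isnan(vals)]
        if vals.size and float(np.mean(vals)) >= observed:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)


def acer_from_expression(pairs: Iterable[tuple[str, str]], expr: ExpressionMatrix,
                         condition_idx: np.ndarray | None = None,
                         label: str = "edge_set") -> ACErResult:
    """ACEr computed per pair directly from expression profiles.

    Restricting ``condition_idx`` recomputes co-expression over that
    condition subset.  With all conditions the result agrees with
    ``acer(pairs, compute_coexpression(expr))`` to numerical precision, and
    is bitwise-reproducible for a given column selection (this is the kernel
    :func:`sensitivity_resample` uses).
    """
    plist = _sorted_pairs(pairs)
    if not plist:
        raise ValidationError("empty pair set")
    gidx = expr.gene_index()
    keep = [(g1, g2) for g1, g2 in plist if g1 in gidx and g2 in gidx]
    n_skipped = len(plist) - len(keep)
    if not keep:
        raise ValidationError(f"{label}: no pair genes present in the expression matrix")
    genes = sorted({g for p in keep for g in p})
    sub_idx = {g: i for i, g in enumerate(genes)}
    values = expr.values[np.asarray([gidx[g] for g in genes], dtype=np.intp)]
    if condition_idx is not None:
        # ascontiguousarray keeps reduction order identical to the all-columns
        # path (column fancy-indexing can return Fortran-ordered arrays)
        values = np.ascontiguousarray(values[:, np.asarray(condition_idx, dtype=np.intp)])
        if values.shape[1] < 2:
            raise ValidationError("need >= 2 conditions to correlate")
    centered, norms = _standardize_rows(values)
    ii = np.asarray([sub_idx[g1] for g1, _ in keep], dtype=np.intp)
    jj = np.asarray([sub_idx[g2] for _, g2 in keep], dtype=np.intp)
    denom = norms[ii] * norms[jj]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", centered[ii], centered[jj]) / denom
    r = np.where(denom > 0, r, np.nan)
    np.clip(r, -1.0, 1.0, out=r)
    defined = ~np.isnan(r)
    used = r[defined]
    n_skipped += int((~defined).sum())
    if used.size == 0:
        raise ValidationError(f"{label}: no usable pairs (constant profiles)")
    return ACErResult(
        acer=float(np.mean(used)),
        n_pairs_used=int(used.size),
        n_pairs_skipped=n_skipped,
        edge_set_label=label,
    )


def sensitivity_resample(pairs: Iterable[tuple[str, str]], expr: ExpressionMatrix,
                         n_conditions: int, n_replicates: int, seed: int = 0,
                         label: str = "edge_set") -> SensitivityDistribution:
    """Condition-subsampling sensitivity analysis of an edge set's ACEr.

    Each replicate draws ``n_conditions`` condition columns without
    replacement (columns are independent across replicates), recomputes
    co-expression on that subset, and records the edge set's ACEr.  With
    ``n_conditions`` equal to the total condition count every replicate
    reproduces the full-data ACEr exactly.
    """
    total = expr.n_conditions
    if n_conditions < 3:
        raise ValidationError("n_conditions must be >= 3")
    if n_conditions > total:
        raise ValidationError(f"n_conditions={n_conditions} exceeds {total} available conditions")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates, dtype=np.float64)
    for rep in range(n_replicates):
        cols = np.sort(rng.choice(total, size=n_conditions, replace=False))
        out[rep] = acer_from_expression(pairs, expr, condition_idx=cols, label=label).acer
    return SensitivityDistribution(
        replicate_acers=out,
        n_conditions=n_conditions,
        n_replicates=n_replicates,
        seed=seed,
        edge_set_label=label,
    )
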