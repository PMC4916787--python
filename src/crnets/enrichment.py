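"""Hypergeometric over-representation of gene sets against term annotations.

Mirrors a GO-style enrichment at a raw p-value threshold (the analysis
convention here is P < 0.01 without multiplicity correction); Benjamini-
Hochberg adjusted values are computed and reported alongside but are not
used for filtering unless the caller opts in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._pairs import Pair
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """Gene -> term annotations with an explicit background universe."""

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]]
    background: frozenset[str]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                if gene not in self.term_to_genes.get(t, ()):  # consistency
                    raise ValidationError(f"inconsistent mappings for gene {gene}, term {t}")
        annotated = set(self.gene_to_terms)
        if not annotated <= set(self.background):
            missing = sorted(annotated - set(self.background))[:5]
            raise ValidationError(f"annotated genes outside background, e.g. {missing}")

    @classmethod
    def from_gene_terms(cls, gene_to_terms: Mapping[str, Iterable[str]],
                        background: Iterable[str] | None = None,
                        term_names: Mapping[str, str] | None = None) -> "AnnotationMap":
        g2t = {g: set(ts) for g, ts in gene_to_terms.items() if ts}
        t2g: dict[str, set[str]] = {}
        for g, ts in g2t.items():
            for t in ts:
                t2g.setdefault(t, set()).add(g)
        bg = frozenset(background) if background is not None else frozenset(g2t)
        return cls(gene_to_terms=g2t, term_to_genes=t2g, background=bg,
                   term_names=dict(term_names or {}))


@dataclass
class EnrichmentResult:
    """One term's overlap with the query set and its upper-tail p-value."""

    term_id: str
    k: int  # overlap
    n: int  # query size
    K: int  # term size in background
    N: int  # background size
    p_value: float
    p_bh: float | None = None
    term_name: str = ""

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValidationError(f"{self.term_id}: overlap {self.k} exceeds min(n, K)")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"{self.term_id}: p-value {self.p_value} outside (0, 1]")


def read_annotation(path, background: Iterable[str] | None = None) -> AnnotationMap:
    """Read ``gene<TAB>term_id[<TAB>term_name]`` rows (header auto-skipped)."""
    path = Path(path)
    g2t: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >= 2 columns")
            gene, term = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (gene.lower(), term.lower()) == ("gene", "term"):
                continue
            g2t.setdefault(gene, set()).add(term)
            if len(fields) > 2 and fields[2].strip():
                names[term] = fields[2].strip()
    return AnnotationMap.from_gene_terms(g2t, background=background, term_names=names)


def genes_of_pairs(pairs: Iterable[Pair]) -> set[str]:
    """Union of both members of every pair."""
    return {g for p in pairs for g in p}


def hypergeom_enrich(query: Iterable[str], ann: AnnotationMap,
                     alpha: float = 0.01, use_bh: bool = False) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of the query set against every term.

    For each term with overlap k >= 1, p = P(X >= k | N, K, n) where N is
    the background size, K the term size and n the query size.  Results
    passing the threshold (raw p by default, BH-adjusted with ``use_bh``)
    are returned sorted ascending by p, ties broken by term id.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    query_set = set(query)
    if not query_set:
        return []
    offenders = sorted(query_set - set(ann.background))
    if offenders:
        raise ValidationError(f"query genes outside background: {offenders}")
    N = len(ann.background)
    n = len(query_set)
    rows: list[EnrichmentResult] = []
    for term in sorted(ann.term_to_genes):
        term_genes = ann.term_to_genes[term] & set(ann.background)
        K = len(term_genes)
        k = len(query_set & term_genes)
        if k == 0:
            continue
        # clamp into (0, 1]: sf can hit exact 0.0 by underflow, 1+eps by rounding
        p = min(max(float(hypergeom.sf(k - 1, N, K, n)), 5e-324), 1.0)
        rows.append(EnrichmentResult(
            term_id=term, k=k, n=n, K=K, N=N, p_value=p,
            term_name=ann.term_names.get(term, ""),
        ))
    if not rows:
        return []
    p_bh = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
    for r, adj in zip(rows, p_bh):
        r.p_bh = float(adj)
    kept = [r for r in rows if (r.p_bh if use_bh else r.p_value) < alpha]
    return sorted(kept, key=lambda r: (r.p_value, r.term_id))


def enrichment_to_tsv(results: list[EnrichmentResult], path) -> None:
    df = pd.DataFrame(
        [(r.term_id, r.term_name, r.k, r.n, r.K, r.N, r.p_value, r.p_bh) for r in results],
        columns=["term", "name", "k", "n", "K", "N", "p", "p_bh"],
    )
    df.to_csv(path, sep="\t", index=False)
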