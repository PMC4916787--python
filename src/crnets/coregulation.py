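"""Co-regulation scoring and top-per-mille co-regulated network construction.

Two genes are "co-regulated" to the extent that their regulator sets agree.
Each association network is first transcribed into a binary regulator
incidence matrix (regulators x genes; TFs for TR networks, first upstream
PPI neighbours for a PPI network).  The co-regulation similarity of a gene
pair is the Pearson correlation of their binary incidence columns — i.e.
the phi coefficient of the 2x2 contingency table of shared/unshared
regulators.  On binary columns the Spearman alternative is mathematically
identical (midranks of a 0/1 vector are an affine function of its values),
so both methods are offered and coincide to machine precision.

A co-regulated network (CRnet) keeps the top ``permille`` fraction-of-1000
highest-scoring pairs among all pairs with defined similarity.  Genes with
no recorded regulator have constant (all-zero) incidence columns; their
pairs are undefined and excluded *before* the per-mille denominator is
taken.  Self-pairs are never candidates (their correlation is 1 trivially).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._pairs import Pair, canonical_pair, condensed_to_ij, n_choose_2
from .errors import ValidationError
from .network_io import Network, PPINetwork, RegulatoryNetwork

logger = logging.getLogger(__name__)

PairSource = Union["CoregulatedNetwork", Iterable[tuple[str, str]]]


@dataclass
class RegulatorMatrix:
    """Binary regulators x genes incidence matrix for one network.

    Columns span ALL genes appearing anywhere in the network (a gene with no
    recorded regulator simply has an all-zero column), in lexicographic
    order.  For TR networks rows are TFs; for a PPI network rows are the
    source proteins of the ordered edges ("first upstream neighbours").
    """

    incidence: np.ndarray  # uint8, regulators x genes
    regulator_ids: list[str]
    gene_ids: list[str]
    source_network: str

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.uint8)
        if self.incidence.shape != (len(self.regulator_ids), len(self.gene_ids)):
            raise ValidationError("incidence shape does not match labels")
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValidationError("incidence entries must be 0/1")

    @property
    def n_regulators(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_genes(self) -> int:
        return self.incidence.shape[1]


@dataclass
class SimilarityScores:
    """Co-regulation similarity for every defined unordered gene pair.

    ``gene_ids`` lists the genes with non-constant incidence columns in
    lexicographic order; ``values`` is the condensed upper triangle of their
    correlation matrix, so pair enumeration order is lexicographic.
    ``n_undefined`` counts pairs excluded because at least one gene's column
    had zero variance.
    """

    gene_ids: list[str]
    values: np.ndarray  # condensed, len C(n,2)
    method: str
    n_undefined: int
    source_network: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != n_choose_2(len(self.gene_ids)):
            raise ValidationError("condensed similarity length does not match gene count")

    def __len__(self) -> int:
        return len(self.values)

    def pair_at(self, k: int) -> Pair:
        i, j = condensed_to_ij(np.asarray([k]), len(self.gene_ids))
        return (self.gene_ids[int(i[0])], self.gene_ids[int(j[0])])

    def items(self) -> Iterator[tuple[Pair, float]]:
        n = len(self.gene_ids)
        k = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                yield (self.gene_ids[i], self.gene_ids[j]), float(self.values[k])
                k += 1

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(g1, g2, r) for (g1, g2), r in self.items()]
        return pd.DataFrame(rows, columns=["gene1", "gene2", "similarity"])


@dataclass
class CoregulatedNetwork:
    """Top-per-mille co-regulated gene pairs of one association network."""

    edges: dict[Pair, float]  # canonical pair -> similarity
    cutoff_permille: float
    source_network: str

    @property
    def pairs(self) -> set[Pair]:
        return set(self.edges)

    @property
    def genes(self) -> set[str]:
        return {g for p in self.edges for g in p}

    def __len__(self) -> int:
        return len(self.edges)

    def to_tsv(self, path) -> None:
        """``gene1<TAB>gene2<TAB>similarity`` sorted desc by score, then pair."""
        ordered = sorted(self.edges.items(), key=lambda kv: (-kv[1], kv[0]))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene1\tgene2\tsimilarity\n")
            for (g1, g2), r in ordered:
                fh.write(f"{g1}\t{g2}\t{r!r}\n")

    @classmethod
    def from_tsv(cls, path, cutoff_permille: float = float("nan"),
                 source_network: str = "") -> "CoregulatedNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
        edges = {
            canonical_pair(r.gene1, r.gene2): float(r.similarity)
            for r in df.itertuples()
        }
        return cls(edges=edges, cutoff_permille=cutoff_permille, source_network=source_network)


def build_regulator_matrix(net: Network, symmetrize_ppi: bool = False) -> RegulatorMatrix:
    """Transcribe a network into its binary regulator incidence matrix.

    TR network: entry (i, j) = 1 iff TF i regulates gene j (any evidence row).
    PPI network: entry (i, j) = 1 iff an ordered edge (i, j) exists; with
    ``symmetrize_ppi`` every edge also counts in reverse, making the
    regulator relation undirected.
    """
    if isinstance(net, PPINetwork) and symmetrize_ppi:
        net = net.symmetrized()
    if isinstance(net, RegulatoryNetwork):
        directed = net.directed_pairs
    else:
        directed = net.edges
    if not directed:
        raise ValidationError(f"{net.name}: cannot build a regulator matrix from an empty network")
    genes = sorted({g for e in directed for g in e})
    regulators = sorted({src for src, _ in directed})
    gidx = {g: i for i, g in enumerate(genes)}
    ridx = {r: i for i, r in enumerate(regulators)}
    inc = np.zeros((len(regulators), len(genes)), dtype=np.uint8)
    for src, tgt in directed:
        inc[ridx[src], gidx[tgt]] = 1
    return RegulatorMatrix(
        incidence=inc, regulator_ids=regulators, gene_ids=genes, source_network=net.name
    )


def score_pairs(mat: RegulatorMatrix, method: str = "pearson") -> SimilarityScores:
    """Correlate every unordered pair of gene columns of the incidence matrix.

    ``method`` is ``"pearson"`` (the phi coefficient on binary data) or
    ``"spearman"`` (correlation of column midranks).  Zero-variance columns
    (genes whose regulator profile is constant) are excluded and the pairs
    they would have formed are counted in ``n_undefined``.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown similarity method {method!r}")
    if mat.n_regulators < 2:
        raise ValidationError("need >= 2 regulators to correlate regulator profiles")
    if mat.n_genes < 2:
        raise ValidationError("need >= 2 genes to form pairs")
    # order columns lexicographically: condensed pair order then doubles as
    # the deterministic tie-break order, whatever order the matrix came in
    col_order = sorted(range(mat.n_genes), key=lambda i: mat.gene_ids[i])
    gene_ids = [mat.gene_ids[i] for i in col_order]
    X = mat.incidence[:, col_order].astype(np.float64)
    if method == "spearman":
        X = rankdata(X, axis=0)
    centered = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", centered, centered))
    defined = norms > 0
    n_all = mat.n_genes
    n_def = int(defined.sum())
    n_undefined = n_choose_2(n_all) - n_choose_2(n_def)
    if n_undefined:
        logger.info(
            "%s: %d of %d columns constant; %d pairs undefined",
            mat.source_network, n_all - n_def, n_all, n_undefined,
        )
    # keep defined columns; gene_ids stay sorted so condensed order is
    # lexicographic pair order (the deterministic tie-break relies on this)
    z = centered[:, defined] / norms[defined]
    corr = z.T @ z
    np.clip(corr, -1.0, 1.0, out=corr)
    iu = np.triu_indices(n_def, 1)
    return SimilarityScores(
        gene_ids=[g for g, d in zip(gene_ids, defined) if d],
        values=corr[iu],
        method=method,
        n_undefined=n_undefined,
        source_network=mat.source_network,
    )


def select_top_permille(scores: SimilarityScores, permille: float) -> CoregulatedNetwork:
    """Keep the ``floor(permille/1000 * n_defined_pairs)`` top-scoring pairs.

    Ties at the threshold are resolved deterministically in lexicographic
    gene-pair order.  The analysis convention uses permille in [1, 5]; any
    value in (0, 1000] is accepted.
    """
    if not (0 < permille <= 1000):
        raise ValidationError(f"permille must be in (0, 1000], got {permille}")
    n = len(scores)
    if n == 0:
        raise ValidationError("no scored pairs to select from")
    k = math.floor(permille / 1000.0 * n)
    if k < 1:
        raise ValidationError(
            f"cutoff yields empty network (permille={permille}, {n} candidate pairs)"
        )
    # stable sort on descending score; condensed order is lexicographic, so
    # equal scores fall back to lexicographically smaller pairs first
    order = np.argsort(-scores.values, kind="stable")[:k]
    i, j = condensed_to_ij(order, len(scores.gene_ids))
    edges = {
        (scores.gene_ids[int(a)], scores.gene_ids[int(b)]): float(scores.values[int(idx)])
        for a, b, idx in zip(i, j, order)
    }
    return CoregulatedNetwork(
        edges=edges, cutoff_permille=float(permille), source_network=scores.source_network
    )


def _as_pair_set(net: PairSource) -> set[Pair]:
    if isinstance(net, CoregulatedNetwork):
        return net.pairs
    return {canonical_pair(a, b) for a, b in net}


def intersect_crnets(nets: Sequence[PairSource]) -> set[Pair]:
    """Unordered-pair intersection of >= 2 edge sets (scores dropped)."""
    if len(nets) < 2:
        raise ValidationError("intersection requires at least two edge sets")
    out = _as_pair_set(nets[0])
    for net in nets[1:]:
        out &= _as_pair_set(net)
    return out


def overlap_table(nets: Sequence[PairSource], names: Sequence[str] | None = None) -> dict[str, int]:
    """Counts of every exclusive region of the 2- or 3-set Venn partition.

    Keys are single names for exclusive regions and ``&``-joined names for
    intersections; values sum to the size of the union.
    """
    if not 2 <= len(nets) <= 3:
        raise ValidationError("overlap_table supports 2 or 3 edge sets")
    sets = [_as_pair_set(n) for n in nets]
    if names is None:
        names = [
            n.source_network if isinstance(n, CoregulatedNetwork) else f"set{i + 1}"
            for i, n in enumerate(nets)
        ]
    if len(names) != len(sets):
        raise ValidationError("names length must match number of edge sets")
    union: set[Pair] = set().union(*sets)
    table: dict[str, int] = {}
    for mask in range(1, 2 ** len(sets)):
        members = [i for i in range(len(sets)) if mask >> i & 1]
        region = set(union)
        for i in range(len(sets)):
            region &= sets[i] if i in members else (union - sets[i])
        table["&".join(names[i] for i in members)] = len(region)
    return table
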