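"""Reading, validating, filtering and writing TR and PPI edge lists.

Transcriptional-regulatory (TR) edges are directed regulator->target pairs
carrying an evidence tag: ``binding`` (TF-DNA binding experiments such as
ChIP-chip) or ``expression`` (targets identified by perturbing the TF).  The
two evidence classes describe different regulatory events and are kept as
separate networks (conventionally "Bnet" and "Enet").

Protein-protein interaction (PPI) edges are stored as ORDERED pairs: the
recorded interactor order defines each gene's "first upstream neighbours"
(the sources of edges pointing at it), which play the role TFs play in the
TR networks.  PPIs are biologically undirected, so symmetrisation is offered
downstream as an explicit option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from ._pairs import Pair, canonical_pair
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

EVIDENCE_BINDING = "binding"
EVIDENCE_EXPRESSION = "expression"
EVIDENCE_MERGED = "merged"
# "merged" appears only in written output of merge_regulatory; accepting it on
# read keeps write->read round-trips closed.
_EVIDENCE_TOKENS = {EVIDENCE_BINDING, EVIDENCE_EXPRESSION, EVIDENCE_MERGED}

#: header tokens recognised when auto-detecting a PPI header row
_PPI_HEADER_TOKENS = {
    "interactora", "interactorb", "interactor_a", "interactor_b",
    "source", "target", "gene1", "gene2", "genea", "geneb",
    "protein1", "protein2", "a", "b",
}


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A set of directed, evidence-tagged regulator->target edges."""

    edges: frozenset[tuple[str, str, str]]  # (regulator, target, evidence)
    name: str = "TRnet"

    def __post_init__(self) -> None:
        for reg, tgt, ev in self.edges:
            if not reg or not tgt:
                raise ValidationError(f"{self.name}: empty gene id in edge ({reg!r}, {tgt!r})")

    @property
    def regulators(self) -> frozenset[str]:
        return frozenset(e[0] for e in self.edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(e[1] for e in self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return self.regulators | self.targets

    @property
    def directed_pairs(self) -> frozenset[tuple[str, str]]:
        """(regulator, target) pairs, evidence tag dropped."""
        return frozenset((e[0], e[1]) for e in self.edges)

    def interaction_pairs(self) -> set[Pair]:
        """Unordered non-self gene pairs of the network's interactions."""
        return {canonical_pair(r, t) for r, t in self.directed_pairs if r != t}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class PPINetwork:
    """Ordered protein-protein interaction pairs (recorded interactor order)."""

    edges: frozenset[tuple[str, str]]
    name: str = "Pnet"

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if not a or not b:
                raise ValidationError(f"{self.name}: empty gene id in edge ({a!r}, {b!r})")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    @property
    def self_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(e for e in self.edges if e[0] == e[1])

    def interaction_pairs(self) -> set[Pair]:
        return {canonical_pair(a, b) for a, b in self.edges if a != b}

    def symmetrized(self) -> "PPINetwork":
        both = set(self.edges) | {(b, a) for a, b in self.edges}
        return PPINetwork(edges=frozenset(both), name=self.name)

    def __len__(self) -> int:
        return len(self.edges)


Network = Union[RegulatoryNetwork, PPINetwork]


@dataclass(frozen=True)
class GeneUniverse:
    """The measured-gene universe; ordering is fixed (lexicographic)."""

    genes: tuple[str, ...]
    _index: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene universe contains duplicate ids")
        object.__setattr__(self, "genes", tuple(sorted(self.genes)))
        object.__setattr__(self, "_index", frozenset(self.genes))

    @classmethod
    def from_gene_ids(cls, ids: Iterable[str]) -> "GeneUniverse":
        return cls(genes=tuple(ids))

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return len(self.genes)


def _read_rows(path: Path, min_cols: int) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {min_cols} tab-separated "
                    f"columns, found {len(fields)}"
                )
            rows.append((lineno, fields))
    return rows


def read_tr_edges(path, evidence_filter: str = "both", name: str | None = None) -> RegulatoryNetwork:
    """Read a YEASTRACT-style TSV of ``regulator<TAB>target<TAB>evidence`` rows.

    ``evidence_filter`` is ``"binding"``, ``"expression"`` or ``"both"``.
    A header row is auto-detected (its evidence field is not a valid token).
    Duplicate (regulator, target, evidence) rows are dropped with a logged
    count.  Unknown evidence tokens raise :class:`ValidationError`.
    """
    if evidence_filter not in (EVIDENCE_BINDING, EVIDENCE_EXPRESSION, "both"):
        raise ValidationError(f"invalid evidence_filter {evidence_filter!r}")
    path = Path(path)
    rows = _read_rows(path, 3)
    edges: set[tuple[str, str, str]] = set()
    n_dup = 0
    for pos, (lineno, fields) in enumerate(rows):
        reg, tgt, ev = fields[0].strip(), fields[1].strip(), fields[2].strip().lower()
        if ev not in _EVIDENCE_TOKENS:
            if pos == 0:
                logger.debug("%s: treating line %d as header", path, lineno)
                continue
            raise ValidationError(
                f"{path}: line {lineno}: unknown evidence token {fields[2]!r} "
                f"(expected one of {sorted(_EVIDENCE_TOKENS)})"
            )
        edge = (reg, tgt, ev)
        if edge in edges:
            n_dup += 1
        else:
            edges.add(edge)
    if n_dup:
        logger.info("%s: dropped %d duplicate TR rows", path, n_dup)
    if evidence_filter != "both":
        edges = {e for e in edges if e[2] == evidence_filter}
    if name is None:
        name = {"binding": "Bnet", "expression": "Enet", "both": "TRnet"}[evidence_filter]
    return RegulatoryNetwork(edges=frozenset(edges), name=name)


def read_ppi_edges(path, name: str = "Pnet") -> PPINetwork:
    """Read a BioGRID-style TSV reduced to two gene columns (order preserved).

    ``(a, b)`` and ``(b, a)`` are distinct records.  Self-edges are kept but
    flagged in the log; extra columns are ignored with a warning.
    """
    path = Path(path)
    rows = _read_rows(path, 2)
    if not rows:
        logger.warning("%s: empty PPI file; returning empty network", path)
        return PPINetwork(edges=frozenset(), name=name)
    first_fields = [f.strip().lower() for f in rows[0][1][:2]]
    if rows[0][1][0].startswith("#") or all(f in _PPI_HEADER_TOKENS for f in first_fields):
        rows = rows[1:]
    if rows and len(rows[0][1]) > 2:
        logger.warning("%s: ignoring columns beyond the first two", path)
    edges: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    for lineno, fields in rows:
        edge = (fields[0].strip(), fields[1].strip())
        if edge[0] == edge[1]:
            n_self += 1
            logger.info("%s: line %d: self-edge (%s, %s)", path, lineno, *edge)
        if edge in edges:
            n_dup += 1
        else:
            edges.add(edge)
    if n_dup:
        logger.info("%s: dropped %d duplicate PPI rows", path, n_dup)
    return PPINetwork(edges=frozenset(edges), name=name)


def restrict_to_universe(net: Network, universe: GeneUniverse) -> Network:
    """Drop every edge touching a gene outside the measured-gene universe."""
    if len(universe) == 0:
        raise ValidationError("gene universe is empty")
    if isinstance(net, RegulatoryNetwork):
        kept = frozenset(e for e in net.edges if e[0] in universe and e[1] in universe)
        removed = len(net.edges) - len(kept)
        out: Network = RegulatoryNetwork(edges=kept, name=net.name)
    else:
        kept_p = frozenset(e for e in net.edges if e[0] in universe and e[1] in universe)
        removed = len(net.edges) - len(kept_p)
        out = PPINetwork(edges=kept_p, name=net.name)
    if removed:
        logger.info("%s: removed %d edges outside the gene universe", net.name, removed)
    if len(out) == 0:
        logger.warning("%s: no edges remain after universe restriction", net.name)
    return out


def merge_regulatory(nets: list[RegulatoryNetwork], name: str | None = None) -> RegulatoryNetwork:
    """Union of (regulator, target) pairs across networks, evidence tag ``merged``."""
    if len(nets) < 2:
        raise ValidationError("merge_regulatory requires at least two networks")
    pairs = set()
    for net in nets:
        pairs |= set(net.directed_pairs)
    if name is None:
        name = "+".join(n.name for n in nets)
    return RegulatoryNetwork(
        edges=frozenset((r, t, EVIDENCE_MERGED) for r, t in pairs), name=name
    )


def write_tr_edges(net: RegulatoryNetwork, path) -> None:
    """Write a sorted, deduplicated TR TSV (reproducible diffs)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\tevidence\n")
        for reg, tgt, ev in sorted(net.edges):
            fh.write(f"{reg}\t{tgt}\t{ev}\n")


def write_ppi_edges(net: PPINetwork, path) -> None:
    """Write a sorted, deduplicated PPI TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("interactorA\tinteractorB\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
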