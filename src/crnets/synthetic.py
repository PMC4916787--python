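"""Synthetic study generator: planted co-regulated, co-expressed modules.

Emulates the statistical structure the pipeline is designed to detect: a
set of gene modules whose members (a) share a dedicated regulator set in
one or all of the three association networks (two TR-like, one PPI-like)
and (b) are co-expressed through a single latent factor per module, so the
population within-module expression correlation is exactly ``rho``:

    x_g = sqrt(rho) * f_m + sqrt(1 - rho) * eps_g,   f_m, eps_g ~ N(0, 1)

Background genes are pure noise; background network edges are independent
Bernoulli draws.  TFs are drawn from the tail of the gene list so that TR
edges survive restriction to the measured-gene universe, as in real data
where TFs are themselves measured genes.  All randomness flows from one
seed through named SeedSequence streams, so components are independently
reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._pairs import Pair, canonical_pair
from .errors import ValidationError
from .expression import ExpressionMatrix
from .network_io import (
    EVIDENCE_BINDING,
    EVIDENCE_EXPRESSION,
    PPINetwork,
    RegulatoryNetwork,
    write_ppi_edges,
    write_tr_edges,
)

logger = logging.getLogger(__name__)

NETWORK_LABELS = ("Bnet", "Enet", "Pnet")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the package's standard evaluation conditions: 600 genes
    (60 of which double as TFs), 400 conditions, six 10-gene modules with
    within-module correlation 0.8, five shared regulators per module per
    network, 1% background edge density, and half the modules planted in
    all three networks (the rest in one network each).
    """

    n_genes: int = 600
    n_tfs: int = 60
    n_conditions: int = 400
    n_modules: int = 6
    module_size: int = 10
    rho: float = 0.8
    regs_per_module: int = 5
    p_background_edge: float = 0.01
    cross_network_overlap: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValidationError("n_modules * module_size exceeds n_genes")
        if self.n_modules * self.module_size + self.n_tfs > self.n_genes:
            raise ValidationError(
                "module genes and the TF pool must not overlap: "
                "n_modules*module_size + n_tfs must be <= n_genes"
            )
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("rho must be in [0, 1)")
        if not 0.0 <= self.p_background_edge <= 1.0:
            raise ValidationError("p_background_edge must be in [0, 1]")
        if not 0.0 <= self.cross_network_overlap <= 1.0:
            raise ValidationError("cross_network_overlap must be in [0, 1]")
        if self.n_conditions < 2:
            raise ValidationError("n_conditions must be >= 2")
        if self.n_modules > 0 and self.module_size < 2:
            raise ValidationError("module_size must be >= 2")
        if self.n_modules > 0 and self.regs_per_module < 1:
            raise ValidationError("regs_per_module must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth of the planted modules."""

    module_assignments: dict[str, int]  # module genes only
    planted_pairs_per_network: dict[str, set[Pair]]
    planted_pairs_all: set[Pair]

    def __post_init__(self) -> None:
        for label, pairs in self.planted_pairs_per_network.items():
            if not self.planted_pairs_all <= pairs:
                raise ValidationError(f"planted_pairs_all not a subset of {label}'s pairs")


@dataclass
class StudyData:
    """One simulated study: expression + three networks + planted truth."""

    expression: ExpressionMatrix
    bnet: RegulatoryNetwork
    enet: RegulatoryNetwork
    pnet: PPINetwork
    truth: PlantedTruth
    config: SynthConfig

    @property
    def networks(self):
        return (self.bnet, self.enet, self.pnet)


def _stream(seed_seq: np.random.SeedSequence, label: str) -> np.random.Generator:
    """Named child stream: one master seed, reproducible per component."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed_seq.entropy, spawn_key=(zlib.crc32(label.encode()),))
    )


def _module_pairs(genes: list[str]) -> set[Pair]:
    return {canonical_pair(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]}


def simulate_study(cfg: SynthConfig) -> StudyData:
    """Generate expression, Bnet/Enet/Pnet and planted truth from one seed."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)

    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    module_genes = [
        genes[m * cfg.module_size:(m + 1) * cfg.module_size] for m in range(cfg.n_modules)
    ]
    module_assignments = {g: m for m, gs in enumerate(module_genes) for g in gs}
    tf_pool = genes[cfg.n_genes - cfg.n_tfs:]
    # PPI sources come from non-module genes (includes the TF-pool ids; the
    # three networks still get distinct per-module regulator draws)
    ppi_source_pool = genes[cfg.n_modules * cfg.module_size:]

    # --- module planting --------------------------------------------------
    n_shared = int(round(cfg.cross_network_overlap * cfg.n_modules))
    planted_in: dict[int, tuple[str, ...]] = {}
    for m in range(cfg.n_modules):
        if m < n_shared:
            planted_in[m] = NETWORK_LABELS
        else:
            planted_in[m] = (NETWORK_LABELS[(m - n_shared) % 3],)

    # --- expression -------------------------------------------------------
    rng_expr = _stream(root, "expression")
    eps = rng_expr.standard_normal((cfg.n_genes, cfg.n_conditions))
    values = eps.copy()
    if cfg.n_modules:
        factors = rng_expr.standard_normal((cfg.n_modules, cfg.n_conditions))
        gidx = {g: i for i, g in enumerate(genes)}
        for m, gs in enumerate(module_genes):
            rows = [gidx[g] for g in gs]
            values[rows] = (
                np.sqrt(cfg.rho) * factors[m] + np.sqrt(1.0 - cfg.rho) * eps[rows]
            )
    conditions = [f"c{j:04d}" for j in range(1, cfg.n_conditions + 1)]
    expression = ExpressionMatrix(values=values, gene_ids=genes, condition_ids=conditions)

    # --- networks ---------------------------------------------------------
    def planted_edges(label: str, pool: list[str]) -> set[tuple[str, str]]:
        rng = _stream(root, f"{label}-planted")
        modules_here = [m for m in range(cfg.n_modules) if label in planted_in[m]]
        need = len(modules_here) * cfg.regs_per_module
        if need > len(pool):
            raise ValidationError(
                f"{label}: regulator pool of {len(pool)} too small for "
                f"{len(modules_here)} modules x {cfg.regs_per_module} regulators"
            )
        draw = rng.choice(len(pool), size=need, replace=False)
        edges: set[tuple[str, str]] = set()
        for mi, m in enumerate(modules_here):
            regs = [pool[k] for k in draw[mi * cfg.regs_per_module:(mi + 1) * cfg.regs_per_module]]
            for reg in regs:
                for g in module_genes[m]:
                    edges.add((reg, g))
        return edges

    def background_edges(label: str, sources: list[str]) -> set[tuple[str, str]]:
        rng = _stream(root, f"{label}-background")
        mask = rng.random((len(sources), cfg.n_genes)) < cfg.p_background_edge
        edges = set()
        for si, gi in zip(*np.nonzero(mask)):
            src, tgt = sources[si], genes[gi]
            if src != tgt:
                edges.add((src, tgt))
        return edges

    # Background edges may originate from any gene (not only the planted-TF
    # pool): each gene column then carries ~p*n_genes random regulators, like
    # the per-gene regulator counts of real curated networks.  A TF-only
    # background grid at the same density leaves most genes with <=1 recorded
    # regulator, and sparse binary profiles collide at phi == 1 by chance.
    tr_nets: dict[str, RegulatoryNetwork] = {}
    for label, evidence in (("Bnet", EVIDENCE_BINDING), ("Enet", EVIDENCE_EXPRESSION)):
        pairs = planted_edges(label, tf_pool) | background_edges(label, genes)
        tr_nets[label] = RegulatoryNetwork(
            edges=frozenset((r, t, evidence) for r, t in pairs), name=label
        )
    ppi_pairs = planted_edges("Pnet", ppi_source_pool) | background_edges("Pnet", genes)
    pnet = PPINetwork(edges=frozenset(ppi_pairs), name="Pnet")

    # --- truth ------------------------------------------------------------
    per_network = {
        label: set().union(*(
            _module_pairs(module_genes[m])
            for m in range(cfg.n_modules) if label in planted_in[m]
        )) if cfg.n_modules else set()
        for label in NETWORK_LABELS
    }
    planted_all = set().union(*(
        _module_pairs(module_genes[m]) for m in range(n_shared)
    )) if n_shared else set()
    truth = PlantedTruth(
        module_assignments=module_assignments,
        planted_pairs_per_network=per_network,
        planted_pairs_all=planted_all,
    )
    return StudyData(
        expression=expression, bnet=tr_nets["Bnet"], enet=tr_nets["Enet"],
        pnet=pnet, truth=truth, config=cfg,
    )


def make_annotation(study: StudyData) -> dict[str, set[str]]:
    """Module-membership terms plus one broad term over all genes."""
    g2t: dict[str, set[str]] = {g: {"ALL_GENES"} for g in study.expression.gene_ids}
    for g, m in study.truth.module_assignments.items():
        g2t[g].add(f"MOD{m:02d}")
    return g2t


FIXTURE_FILES = (
    "expression.tsv", "tr_edges.tsv", "ppi_edges.tsv", "annotation.tsv", "truth.json",
)


def write_fixture(directory, study: StudyData, force: bool = False) -> dict[str, Path]:
    """Emit the TSV fixture directory consumed by the I/O modules.

    Both TR networks go into one YEASTRACT-style file distinguished by the
    evidence column.  Floats are written at full round-trip precision, so
    re-reading reproduces the generated objects exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / name for name in FIXTURE_FILES}
    existing = [p.name for p in paths.values() if p.exists()]
    if existing and not force:
        raise ValidationError(f"fixture files already exist (use force=True): {existing}")

    study.expression.to_tsv(paths["expression.tsv"])
    merged_tr = RegulatoryNetwork(
        edges=study.bnet.edges | study.enet.edges, name="TRnet"
    )
    write_tr_edges(merged_tr, paths["tr_edges.tsv"])
    write_ppi_edges(study.pnet, paths["ppi_edges.tsv"])

    annotation = make_annotation(study)
    with open(paths["annotation.tsv"], "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for g in study.expression.gene_ids:
            for t in sorted(annotation[g]):
                fh.write(f"{g}\t{t}\n")

    truth = {
        "module_assignments": dict(sorted(study.truth.module_assignments.items())),
        "planted_pairs_per_network": {
            label: sorted(list(p) for p in pairs)
            for label, pairs in sorted(study.truth.planted_pairs_per_network.items())
        },
        "planted_pairs_all": sorted(list(p) for p in study.truth.planted_pairs_all),
        "config": asdict(study.config),
    }
    with open(paths["truth.json"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def load_truth(path) -> PlantedTruth:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return PlantedTruth(
        module_assignments={g: int(m) for g, m in data["module_assignments"].items()},
        planted_pairs_per_network={
            label: {canonical_pair(a, b) for a, b in pairs}
            for label, pairs in data["planted_pairs_per_network"].items()
        },
        planted_pairs_all={canonical_pair(a, b) for a, b in data["planted_pairs_all"]},
    )
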