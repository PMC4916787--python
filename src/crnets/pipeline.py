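"""End-to-end orchestration: inputs -> CRnets -> ACEr -> sensitivity -> enrichment.

``run_pipeline`` executes the full analysis from a single config and writes
a deterministic machine-readable summary plus per-stage artifacts, so any
later stage can be re-run in isolation.  Identical config + seed produce a
byte-identical summary (sorted keys, no timestamps in the payload).
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._pairs import Pair
from .coregulation import (
    CoregulatedNetwork,
    build_regulator_matrix,
    intersect_crnets,
    overlap_table,
    score_pairs,
    select_top_permille,
)
from .enrichment import enrichment_to_tsv, genes_of_pairs, hypergeom_enrich, read_annotation
from .errors import CrnetsError, ValidationError
from .expression import collapse_orfs, compute_coexpression, read_expression
from .netstats import ACErResult, acer, acer_permutation_test, reference_acer, sensitivity_resample
from .network_io import (
    GeneUniverse,
    merge_regulatory,
    read_ppi_edges,
    read_tr_edges,
    restrict_to_universe,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (YAML-serialisable)."""

    expression_path: str
    tr_path: str
    ppi_path: str
    annotation_path: str | None = None
    orf_map_path: str | None = None
    out_dir: str = "crnets_out"
    permille: float = 5.0
    method: str = "pearson"
    symmetrize_ppi: bool = False
    n_perm: int = 999
    sensitivity_n_conditions: int = 100
    sensitivity_n_replicates: int = 1000
    enrichment_alpha: float = 0.01
    merged_mode: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("expression_path", "tr_path", "ppi_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise ValidationError(f"{attr}: file not found: {p}")
        for attr in ("annotation_path", "orf_map_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{attr}: file not found: {p}")
        if self.method not in ("pearson", "spearman"):
            raise ValidationError(f"invalid method {self.method!r}")
        if not 0 < self.permille <= 1000:
            raise ValidationError("permille must be in (0, 1000]")
        if self.n_perm < 1 or self.sensitivity_n_replicates < 1:
            raise ValidationError("n_perm and sensitivity_n_replicates must be >= 1")


def stage_seed(base_seed: int, label: str) -> int:
    """Deterministic per-stage seed derived from the run seed and a label."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(zlib.crc32(label.encode()),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _acer_entry(res: ACErResult) -> dict:
    return {
        "acer": res.acer,
        "n_pairs_used": res.n_pairs_used,
        "n_pairs_skipped": res.n_pairs_skipped,
        "p_value": res.p_value,
        "n_perm": res.n_perm,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole analysis; returns the summary dict (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}}
    stage = _StageTimer()

    with stage("load-expression"):
        expr = read_expression(cfg.expression_path)
        if cfg.orf_map_path:
            mapping = _read_orf_map(cfg.orf_map_path)
            expr = collapse_orfs(expr, mapping)
        elif len(set(expr.gene_ids)) != len(expr.gene_ids):
            raise ValidationError("duplicate gene ids in expression matrix; supply an ORF map")
        universe = GeneUniverse.from_gene_ids(expr.gene_ids)
        summary["n_genes"] = expr.n_genes
        summary["n_conditions"] = expr.n_conditions

    with stage("load-networks"):
        nets = [
            restrict_to_universe(read_tr_edges(cfg.tr_path, "binding", name="Bnet"), universe),
            restrict_to_universe(read_tr_edges(cfg.tr_path, "expression", name="Enet"), universe),
            restrict_to_universe(read_ppi_edges(cfg.ppi_path, name="Pnet"), universe),
        ]
        summary["network_sizes"] = {
            n.name: {"edges": len(n), "genes": len(n.genes)} for n in nets
        }

    with stage("coexpression"):
        coexpr = compute_coexpression(expr)
        coexpr.save(out / "coexpression.npy", out / "coexpression_genes.tsv")

    acer_entries: dict[str, dict] = {}

    def scored_acer(pairs: set[Pair], label: str) -> None:
        res = acer(pairs, coexpr, label=label)
        res.seed = stage_seed(cfg.seed, f"perm-{label}")
        res.n_perm = cfg.n_perm
        res.p_value = acer_permutation_test(
            pairs, coexpr, n_perm=cfg.n_perm, seed=res.seed, label=label
        )
        acer_entries[label] = _acer_entry(res)

    with stage("reference-acer"):
        acer_entries["reference"] = _acer_entry(reference_acer(coexpr))

    with stage("association-acer"):
        for net in nets:
            scored_acer(net.interaction_pairs(), net.name)

    with stage("coregulation"):
        crnets: dict[str, CoregulatedNetwork] = {}
        for net in nets:
            mat = build_regulator_matrix(net, symmetrize_ppi=cfg.symmetrize_ppi)
            scores = score_pairs(mat, method=cfg.method)
            crnet = select_top_permille(scores, cfg.permille)
            crnet.to_tsv(out / f"{net.name}_crnet.tsv")
            crnets[net.name] = crnet
        summary["crnet_sizes"] = {
            f"{k}CR": {"edges": len(v), "genes": len(v.genes)} for k, v in crnets.items()
        }
        summary["crnet_overlap"] = overlap_table(
            list(crnets.values()), names=[f"{k}CR" for k in crnets]
        )

    with stage("crnet-acer"):
        for label, crnet in crnets.items():
            scored_acer(crnet.pairs, f"{label}CR")

    with stage("intersections"):
        combos = [("Bnet", "Enet"), ("Bnet", "Pnet"), ("Enet", "Pnet"),
                  ("Bnet", "Enet", "Pnet")]
        triple: set[Pair] = set()
        for combo in combos:
            label = "&".join(f"{c}CR" for c in combo)
            inter = intersect_crnets([crnets[c] for c in combo])
            if len(combo) == 3:
                triple = inter
                _write_pairs(inter, out / "triple_intersection.tsv")
            if inter:
                scored_acer(inter, label)
            else:
                acer_entries[label] = {
                    "acer": None, "n_pairs_used": 0, "n_pairs_skipped": 0,
                    "p_value": None, "n_perm": None,
                }
                logger.warning("intersection %s is empty; no ACEr computed", label)

    summary["acer"] = acer_entries

    with stage("sensitivity"):
        if triple:
            n_cond = min(cfg.sensitivity_n_conditions, expr.n_conditions)
            dist = sensitivity_resample(
                triple, expr,
                n_conditions=n_cond,
                n_replicates=cfg.sensitivity_n_replicates,
                seed=stage_seed(cfg.seed, "sensitivity"),
                label="BnetCR&EnetCR&PnetCR",
            )
            dist.to_tsv(out / "sensitivity_replicates.tsv")
            summary["sensitivity"] = {
                "mean": dist.mean, "std": dist.std,
                "n_conditions": dist.n_conditions,
                "n_replicates": dist.n_replicates, "seed": dist.seed,
            }
        else:
            summary["sensitivity"] = None

    with stage("enrichment"):
        if triple and cfg.annotation_path:
            ann = read_annotation(cfg.annotation_path, background=expr.gene_ids)
            results = hypergeom_enrich(
                genes_of_pairs(triple), ann, alpha=cfg.enrichment_alpha
            )
            enrichment_to_tsv(results, out / "enrichment.tsv")
            summary["enrichment"] = [
                {"term": r.term_id, "k": r.k, "K": r.K, "p": r.p_value, "p_bh": r.p_bh}
                for r in results
            ]
        else:
            summary["enrichment"] = None

    if cfg.merged_mode:
        with stage("merged-network"):
            merged = merge_regulatory([nets[0], nets[1]], name="Mnet")
            mat = build_regulator_matrix(merged)
            mcrnet = select_top_permille(score_pairs(mat, method=cfg.method), cfg.permille)
            mcrnet.to_tsv(out / "Mnet_crnet.tsv")
            summary["crnet_sizes"]["MnetCR"] = {
                "edges": len(mcrnet), "genes": len(mcrnet.genes)
            }
            scored_acer(mcrnet.pairs, "MnetCR")
            inter_mp = intersect_crnets([mcrnet, crnets["Pnet"]])
            if inter_mp:
                scored_acer(inter_mp, "MnetCR&PnetCR")
            summary["acer"] = acer_entries

    summary_path = out / "summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete; summary at %s", summary_path)
    return summary


def _read_orf_map(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}: line {lineno}: expected orf<TAB>gene")
            if lineno == 1 and fields[0].lower() in ("orf", "id"):
                continue
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def _write_pairs(pairs: set[Pair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\n")
        for g1, g2 in sorted(pairs):
            fh.write(f"{g1}\t{g2}\n")


class _StageTimer:
    """Context-manager factory logging per-stage wall time and failures."""

    def __call__(self, name: str):
        return _Stage(name)


class _Stage:
    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
            return False
        logger.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
        if not issubclass(exc_type, CrnetsError):
            return False
        raise CrnetsError(f"stage {self.name} failed: {exc}") from exc
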