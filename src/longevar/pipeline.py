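"""End-to-end orchestration of the staged analysis.

Stages: simulate (or ingest) a cohort -> single-variant Fisher scan ->
gene-based SKAT tests -> functional prioritization and stratified
gene tests -> sub-pathway enrichment -> seed subnetwork extraction.
Every stage writes TSV outputs under the configured directory, and a
JSON manifest records the config snapshot, seeds, and a checksum of
every produced file, so identical config + seed reproduces
byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ValidationError
from .enrichment import significant_genes, subpathway_enrichment
from .io import (
    read_table,
    read_vcf,
    write_edges,
    write_pool_table,
    write_results,
    write_vcf,
)
from .network import build_graph, extract_subnetwork
from .prioritize import build_strata, select_genotyping_candidates
from .simulate import (
    AnnotationConfig,
    Effect,
    MafLaw,
    SimulationConfig,
    make_pooling_plan,
    pool_cohort,
    simulate_annotations,
    simulate_cohort,
)
from .single_variant import single_variant_scan
from .skat import SkatConfig, gene_scan

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a run needs; see ``load_config`` for the YAML form."""

    output_dir: str = "longevar_out"
    seed: int = 0
    vcf: str | None = None  # ingest instead of simulating
    annotations: str | None = None
    gene_sets: str | None = None
    ppi_edges: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    annotation_config: AnnotationConfig = field(default_factory=AnnotationConfig)
    skat: SkatConfig = field(default_factory=SkatConfig)
    alpha_single: float = 0.05
    alpha_gene: float = 0.05
    alpha_enrichment: float = 0.05
    methods: tuple[str, ...] = ("SKAT", "SKAT-O", "SKAT-C")
    stratified: bool = True
    pool_size: int = 50
    pool_depth: float = float("inf")
    n_subnetwork_seeds: int = 10
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("alpha_single", "alpha_gene", "alpha_enrichment"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        for name in ("vcf", "annotations", "gene_sets", "ppi_edges"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ValidationError(f"config input {name}: no such file {path!r}")


def load_config(path: str) -> PipelineConfig:
    """Read a YAML config file into a :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", {})
    if "maf_law" in sim:
        sim["maf_law"] = MafLaw(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in sim["maf_law"].items()
        })
    if "effect_model" in sim:
        sim["effect_model"] = tuple(Effect(**e) for e in sim["effect_model"])
    if "variants_per_gene" in sim and isinstance(sim["variants_per_gene"], list):
        sim["variants_per_gene"] = tuple(sim["variants_per_gene"])
    skat_raw = raw.pop("skat", {})
    for k in ("weight_beta_rare", "weight_beta_common", "rho_grid"):
        if k in skat_raw:
            skat_raw[k] = tuple(skat_raw[k])
    ann_raw = raw.pop("annotation_config", {})
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    return PipelineConfig(
        simulation=SimulationConfig(**sim),
        skat=SkatConfig(**skat_raw),
        annotation_config=AnnotationConfig(**ann_raw),
        **raw,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and np.isinf(obj):
            return "inf"
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    A stage failure aborts the run with the stage name; files already
    written are retained and flagged in the manifest.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _config_snapshot(config),
        "seed": config.seed,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "files": {},
        "status": "running",
    }
    stage = "setup"
    try:
        # ------------------------------------------------ stage: cohort
        stage = "cohort"
        if config.vcf is not None:
            dataset = read_vcf(config.vcf)
            truth = None
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            dataset, truth = simulate_cohort(sim)
            write_vcf(dataset, os.path.join(out, "cohort.vcf"))
            truth.to_csv(os.path.join(out, "truth.tsv"), sep="\t", index=False)
        logger.info("cohort: %d variants x %d individuals", dataset.n_variants, dataset.n_individuals)
        manifest["stages"][stage] = {
            "n_variants": int(dataset.n_variants),
            "n_cases": int((dataset.phenotype == 1).sum()),
            "n_controls": int((dataset.phenotype == 0).sum()),
        }

        # annotations
        stage = "annotations"
        if config.annotations is not None:
            annotations = read_table(config.annotations, "annotations")
        else:
            annotations = simulate_annotations(
                dataset.variants, config.annotation_config, seed=config.seed
            )
            annotations.to_csv(os.path.join(out, "annotations.tsv"), sep="\t", index=False)

        # pooled representation (written for downstream pooled analyses)
        stage = "pooling"
        plan = make_pooling_plan(
            dataset.phenotype, pool_size=config.pool_size,
            depth=config.pool_depth, seed=config.seed,
        )
        pools = pool_cohort(dataset.genotypes, dataset.phenotype, plan, dataset.variants)
        write_pool_table(pools, os.path.join(out, "pool_af.tsv"))

        # ------------------------------------- stage: single-variant scan
        stage = "single_variant"
        scan = single_variant_scan(dataset)
        write_results(
            scan.rename(columns={"p_allelic": "p_allelic", "p_genotypic": "p_genotypic"}),
            os.path.join(out, "single_variant.tsv"),
        )
        n_sig_single = int((scan["p_allelic"] < config.alpha_single).sum())
        manifest["stages"][stage] = {
            "n_tested": int(len(scan)),
            "n_significant": n_sig_single,
            "alpha": config.alpha_single,
        }

        stage = "candidates"
        candidates = select_genotyping_candidates(
            scan, p_cut=config.alpha_single, maf_cut=config.skat.rare_common_threshold
        )
        write_results(candidates, os.path.join(out, "genotyping_candidates.tsv"))
        manifest["stages"][stage] = {"n_selected": int(len(candidates))}

        # ------------------------------------------- stage: strata + gene tests
        stage = "strata"
        strata = build_strata(dataset.variants, annotations) if config.stratified else None
        if strata is not None:
            srows = []
            for name, keys in strata.items():
                for k in sorted(keys):
                    srows.append({"stratum": name, "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3]})
            pd.DataFrame(srows).to_csv(os.path.join(out, "strata.tsv"), sep="\t", index=False)
            manifest["stages"][stage] = {name: len(keys) for name, keys in strata.items()}

        stage = "gene_tests"
        genes = gene_scan(dataset, config.skat, strata=strata, methods=config.methods)
        write_results(genes, os.path.join(out, "gene_tests.tsv"))
        # matrix export: gene x (method, stratum), absent cells marked
        matrix = genes.pivot_table(
            index="gene", columns=["method", "stratum"], values="p", dropna=False
        )
        matrix.columns = [f"{m}-{s}" for m, s in matrix.columns]
        matrix.to_csv(os.path.join(out, "gene_matrix.tsv"), sep="\t", na_rep="absent")
        sig = significant_genes(genes, alpha=config.alpha_gene)
        manifest["stages"][stage] = {
            "n_genes": int(genes["gene"].nunique()),
            "n_significant": len(sig),
            "alpha": config.alpha_gene,
            "methods": list(config.methods),
        }

        # --------------------------------------------- stage: enrichment
        stage = "enrichment"
        universe = sorted(dataset.variants["gene"].unique())
        if config.gene_sets is not None:
            sets = read_table(config.gene_sets, "gene_sets")
        else:
            # default sub-pathways: contiguous blocks of the gene universe
            block = max(2, len(universe) // 10)
            sets = {
                f"subpathway_{i + 1:02d}": universe[i * block : (i + 1) * block]
                for i in range((len(universe) + block - 1) // block)
                if universe[i * block : (i + 1) * block]
            }
        enr = subpathway_enrichment(sig, sets, universe)
        write_results(enr, os.path.join(out, "enrichment.tsv"))
        manifest["stages"][stage] = {
            "n_sets": int(len(enr)),
            "n_enriched": int((enr["p"] < config.alpha_enrichment).sum()) if len(enr) else 0,
        }

        # --------------------------------------------- stage: subnetwork
        stage = "subnetwork"
        if config.ppi_edges is not None:
            edges = read_table(config.ppi_edges, "edges")
        else:
            edges = _synthetic_ppi(universe, seed=config.seed)
        graph = build_graph(edges)
        skat_all = genes[(genes["method"] == genes["method"].iloc[0])]
        if strata is not None:
            skat_all = skat_all[skat_all["stratum"] == "all"]
        seeds = (
            skat_all.dropna(subset=["p"])
            .sort_values(["p", "gene"], kind="mergesort")["gene"]
            .head(config.n_subnetwork_seeds)
            .tolist()
        )
        seeds = [s for s in seeds if s in graph]
        if len(seeds) >= 2:
            sub = extract_subnetwork(graph, seeds)
            pd.DataFrame({"node": sub.nodes, "is_seed": [n in set(sub.seeds) for n in sub.nodes]}).to_csv(
                os.path.join(out, "subnetwork_nodes.tsv"), sep="\t", index=False
            )
            write_edges(sub.edges, os.path.join(out, "subnetwork_edges.tsv"))
            manifest["stages"][stage] = {
                "n_seeds": len(sub.seeds),
                "n_nodes": len(sub.nodes),
                "n_edges": len(sub.edges),
                "cutoff": sub.cutoff,
                "excluded_seeds": sub.excluded_seeds,
            }
        else:
            manifest["stages"][stage] = {"n_seeds": len(seeds), "note": "too few seeds in graph"}

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        _finalize_manifest(manifest, out)
        raise ValidationError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    _finalize_manifest(manifest, out)
    return manifest


def _finalize_manifest(manifest: dict, out: str) -> None:
    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    for fname in sorted(os.listdir(out)):
        path = os.path.join(out, fname)
        if os.path.isfile(path) and fname != "manifest.json":
            manifest["files"][fname] = _sha256(path)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _synthetic_ppi(genes: list[str], seed: int, extra_nodes: int = 30) -> list:
    """Small-world-ish synthetic interactome over the gene universe."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(3,)))
    nodes = list(genes) + [f"HUB{i:02d}" for i in range(extra_nodes)]
    edges = []
    for i, g in enumerate(nodes):
        for _ in range(2):
            j = int(rng.integers(0, len(nodes)))
            if nodes[j] != g:
                edges.append((g, nodes[j]))
    # a few hubs touching many genes keep the graph well connected
    for h in nodes[len(genes) : len(genes) + 5]:
        for g in rng.choice(genes, size=min(10, len(genes)), replace=False):
            edges.append((h, str(g)))
    return edges


def report(manifest: dict) -> str:
    """Human-readable per-stage summary of a (possibly partial) run."""
    lines = [
        f"longevar {manifest.get('version', '?')} run summary",
        f"status: {manifest.get('status', 'unknown')}",
        f"seed: {manifest.get('seed')}",
    ]
    stages = manifest.get("stages", {})
    for name, info in stages.items():
        parts = ", ".join(f"{k}={v}" for k, v in info.items())
        lines.append(f"  {name}: {parts}")
    if not stages:
        lines.append("  (no stages completed)")
    lines.append(f"files written: {len(manifest.get('files', {}))}")
    return "\n".join(lines)
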