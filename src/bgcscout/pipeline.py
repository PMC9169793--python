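"""End-to-end discovery pipeline.

Stages: rank modules by pathogen induction -> select the top k -> mine the
union of their genes for adjacent runs -> classify runs and call candidate
clusters -> bait-centric coexpression per candidate -> TF-network overlay
(per-TF cluster incidence, shared regulators, tandem/homoeolog grouping) ->
GO enrichment of shared-TF targets.  Everything is deterministic given the
inputs and configuration; all stage tables can be written as TSV plus a
machine-readable JSON summary of per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as bio
from .coexpression import bait_coexpression, coherence_summary, report_to_frame
from .induction import induction_scores, scores_to_frame, select_top_modules
from .mining import (
    call_candidate_bgcs,
    candidates_to_frame,
    classify_groups,
    find_adjacent_groups,
    groups_to_frame,
)
from .regnet import (
    attach_groups,
    count_shared_tfs,
    enrichment_to_frame,
    go_enrichment,
    group_tfs,
    summaries_to_frame,
    tf_bgc_incidence,
)
from .types import (
    BgcscoutError,
    CandidateBGC,
    CoexpressionReport,
    ExpressionMatrix,
    GeneTable,
    ModuleSet,
    RegulatoryNetwork,
    SampleMetadata,
)

log = logging.getLogger("bgcscout")


@dataclass
class DiscoveryConfig:
    """Input paths and tunable parameters for one discovery run."""

    annotation: str
    expression: str
    metadata: str
    module_map: str
    network: str | None = None
    go_annotation: str | None = None
    output_dir: str | None = None

    top_k: int = 5
    min_size: int = 3
    max_gap: int = 1
    r_threshold: float = 0.8
    min_bgcs: int | None = None  # None: all called candidates
    transform: str = "log2"
    kinase_fraction: float = 0.5
    tandem_window: int = 5
    include_unassigned: bool = True  # chromosome "U" genes eligible for mining

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscoveryConfig":
        with open(path) as fh:
            obj = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise BgcscoutError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)


@dataclass
class DiscoveryReport:
    """All stage outputs of one discovery run."""

    scores: list
    top_modules: list[str]
    groups: list
    candidates: list[CandidateBGC]
    coexpression: list[CoexpressionReport]
    coherence: pd.DataFrame
    tf_summaries: list
    tf_groups: list[tuple[str, ...]]
    n_shared_tfs: int
    n_shared_tf_groups: int
    enrichment: list
    summary: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except BgcscoutError as exc:
                raise BgcscoutError(f"stage {name}: {exc}") from exc

        return wrapper

    return deco


def discover(
    genome: GeneTable,
    expr: ExpressionMatrix,
    metadata: SampleMetadata,
    modules: ModuleSet,
    network: RegulatoryNetwork | None = None,
    go_annotation: Mapping[str, set[str]] | None = None,
    config: DiscoveryConfig | None = None,
) -> DiscoveryReport:
    """Run all discovery stages on in-memory inputs."""
    cfg = config or DiscoveryConfig(annotation="", expression="", metadata="", module_map="")

    log.info("ranking %d modules", len(modules.module_ids))
    scores = _stage("rank-modules")(induction_scores)(
        expr, modules, metadata, transform=cfg.transform
    )
    top = select_top_modules(scores, k=min(cfg.top_k, len(scores)))

    module_genes = modules.genes_in_any(top)
    if not cfg.include_unassigned:
        module_genes = {g for g in module_genes if g in genome and genome[g].chromosome != "U"}
    log.info("mining %d genes from modules %s", len(module_genes), top)
    groups = _stage("mine-clusters")(find_adjacent_groups)(
        genome, module_genes, min_size=cfg.min_size, max_gap=cfg.max_gap, modules=modules
    )
    groups = classify_groups(groups, genome, kinase_fraction=cfg.kinase_fraction)
    candidates = _stage("mine-clusters")(call_candidate_bgcs)(
        groups, genome, expr=expr, transform=cfg.transform
    )
    log.info("%d adjacency groups, %d candidate clusters", len(groups), len(candidates))

    reports: list[CoexpressionReport] = []
    coherence_rows = []
    for cand in candidates:
        rep = _stage("coexpress")(bait_coexpression)(
            expr, cand, threshold=cfg.r_threshold, transform=cfg.transform
        )
        reports.append(rep)
        row = {"bgc_id": cand.bgc_id, "bait": cand.bait}
        row.update(coherence_summary(rep))
        coherence_rows.append(row)
    coherence = pd.DataFrame(coherence_rows)

    tf_summaries: list = []
    tf_groups_list: list[tuple[str, ...]] = []
    n_shared = n_shared_groups = 0
    enrichment: list = []
    if network is not None and candidates:
        tf_summaries = _stage("tf-overlay")(tf_bgc_incidence)(network, candidates)
        tf_groups_list = group_tfs(
            [s.tf for s in tf_summaries], genome, tandem_window=cfg.tandem_window
        )
        tf_summaries = attach_groups(tf_summaries, tf_groups_list)
        min_bgcs = cfg.min_bgcs if cfg.min_bgcs is not None else len(candidates)
        n_shared, n_shared_groups = count_shared_tfs(tf_summaries, min_bgcs)
        if go_annotation is not None and n_shared:
            shared = [s for s in tf_summaries if s.incidence >= min_bgcs]
            selection: set[str] = set()
            for s in shared:
                selection |= network.targets_of(s.tf)
            background = set(genome.gene_ids)
            selection &= background
            if selection:
                enrichment = _stage("enrich")(go_enrichment)(
                    selection, go_annotation, background
                )

    summary = {
        "n_modules": len(scores),
        "top_modules": top,
        "n_module_genes_mined": len(module_genes),
        "n_adjacency_groups": len(groups),
        "n_kinase_groups": sum(g.classification == "kinase" for g in groups),
        "n_metabolic_groups": sum(g.classification == "metabolic" for g in groups),
        "n_other_groups": sum(g.classification == "other" for g in groups),
        "n_candidate_bgcs": len(candidates),
        "candidate_classes": sorted(c.predicted_class for c in candidates),
        "n_tfs_with_bgc_edge": len(tf_summaries),
        "n_shared_tfs": n_shared,
        "n_shared_tf_groups": n_shared_groups,
        "n_enriched_terms_q05": sum(r.q < 0.05 for r in enrichment),
    }
    return DiscoveryReport(
        scores=scores,
        top_modules=top,
        groups=groups,
        candidates=candidates,
        coexpression=reports,
        coherence=coherence,
        tf_summaries=tf_summaries,
        tf_groups=tf_groups_list,
        n_shared_tfs=n_shared,
        n_shared_tf_groups=n_shared_groups,
        enrichment=enrichment,
        summary=summary,
    )


def write_report(report: DiscoveryReport, outdir: str | Path) -> None:
    """Write all stage tables as TSV plus the JSON count summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bio.write_report_table(scores_to_frame(report.scores), outdir / "modules_ranked.tsv")
    bio.write_report_table(groups_to_frame(report.groups), outdir / "adjacency_groups.tsv")
    bio.write_report_table(candidates_to_frame(report.candidates), outdir / "candidate_bgcs.tsv")
    if report.coexpression:
        coex = pd.concat([report_to_frame(r) for r in report.coexpression], ignore_index=True)
    else:
        coex = pd.DataFrame(
            columns=["bgc_id", "bait", "gene_id", "r", "coexpressed", "n_samples", "threshold"]
        )
    bio.write_report_table(coex, outdir / "coexpression.tsv")
    bio.write_report_table(report.coherence, outdir / "coherence.tsv")
    bio.write_report_table(summaries_to_frame(report.tf_summaries), outdir / "tf_summary.tsv")
    bio.write_report_table(enrichment_to_frame(report.enrichment), outdir / "enrichment.tsv")
    bio.write_json(report.summary, outdir / "summary.json")


def run_discovery(config: DiscoveryConfig) -> DiscoveryReport:
    """Read all configured inputs, run every stage, optionally write tables."""
    genome = _stage("read-annotation")(bio.read_gene_annotation)(config.annotation)
    expr, metadata = _stage("read-expression")(bio.read_expression)(
        config.expression, config.metadata
    )
    modules = _stage("read-modules")(bio.read_module_map)(config.module_map)
    network = bio.read_network(config.network) if config.network else None
    go_annotation = (
        bio.read_go_annotation(config.go_annotation) if config.go_annotation else None
    )
    report = discover(
        genome, expr, metadata, modules,
        network=network, go_annotation=go_annotation, config=config,
    )
    if config.output_dir:
        write_report(report, config.output_dir)
    return report
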