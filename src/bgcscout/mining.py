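"""Adjacency mining: physically adjacent gene runs within selected modules.

"Physically adjacent" is interpreted on chromosome rank order (ordinal gene
position after sorting accession indices), not on base-pair distance or a
fixed accession step, because annotation insertions break fixed spacing.
``max_gap`` = 1 means strictly consecutive ranks; larger values tolerate
interleaved non-module genes, as seen inside real clusters.

Runs are classified by enzyme-family content into kinase arrays, metabolic
groups and the rest; metabolic groups containing a scaffold-forming enzyme
(terpene synthase / copalyl diphosphate synthase, oxidosqualene cyclase, or
chalcone synthase) are called candidate biosynthetic gene clusters with a
product class predicted from the scaffold family.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    AdjacencyGroup,
    BgcscoutError,
    CandidateBGC,
    ExpressionMatrix,
    GeneTable,
    ModuleSet,
    parse_accession,
)

#: Scaffold-forming enzyme families and the product class they diagnose.
SCAFFOLD_CLASS: dict[str, str] = {
    "TPS": "diterpene",
    "KSL": "diterpene",
    "CPS": "diterpene",
    "OSC": "triterpene",
    "CHS": "flavonoid",
}

#: Tailoring-enzyme family prefixes (a label like "CYP71C164" counts as CYP).
TAILORING_PREFIXES: tuple[str, ...] = ("CYP", "UGT", "OMT", "HSD", "SDR", "ACT", "CHI")


def family_category(family: str) -> str:
    """Map an annotation family label to scaffold / tailoring / kinase / tf / other."""
    if family in SCAFFOLD_CLASS:
        return "scaffold"
    if any(family.startswith(p) for p in TAILORING_PREFIXES):
        return "tailoring"
    if family == "kinase":
        return "kinase"
    if family.startswith("TF:"):
        return "tf"
    return "other"


def find_adjacent_groups(
    gene_table: GeneTable,
    module_gene_set: Iterable[str],
    min_size: int = 3,
    max_gap: int = 1,
    modules: ModuleSet | None = None,
) -> list[AdjacencyGroup]:
    """All maximal runs of module genes with consecutive rank gaps <= max_gap.

    Returned in genomic order (chromosome, then rank).  Output depends only
    on ranks, so it is invariant to the order genes appeared in the input
    annotation, and no two returned runs overlap.
    """
    if min_size < 1:
        raise BgcscoutError("min_size must be >= 1")
    if max_gap < 1:
        raise BgcscoutError("max_gap must be >= 1")
    member_set = {g for g in module_gene_set if g in gene_table}
    groups: list[AdjacencyGroup] = []
    counter = 0
    for chrom in gene_table.chromosomes:
        members = [r for r in gene_table.on_chromosome(chrom) if r.gene_id in member_set]
        run: list = []
        for rec in members:
            if run and rec.rank - run[-1].rank > max_gap:
                counter = _flush(run, chrom, min_size, max_gap, modules, groups, counter)
                run = []
            run.append(rec)
        counter = _flush(run, chrom, min_size, max_gap, modules, groups, counter)
    return groups


def _flush(run, chrom, min_size, max_gap, modules, groups, counter) -> int:
    if len(run) >= min_size:
        counter += 1
        member_ids = tuple(r.gene_id for r in run)
        mods: tuple[str, ...] = ()
        if modules is not None:
            mods = tuple(sorted({modules.assignment[g] for g in member_ids if g in modules.assignment}))
        groups.append(
            AdjacencyGroup(
                group_id=f"AG{counter:03d}",
                chromosome=chrom,
                members=member_ids,
                modules=mods,
                max_gap=max_gap,
            )
        )
    return counter


def classify_group(
    group: AdjacencyGroup,
    family_map: Mapping[str, str],
    kinase_fraction: float = 0.5,
) -> str:
    """Classify a run as "kinase", "metabolic" or "other" from member families.

    Kinase: at least ``kinase_fraction`` of members are kinases.  Metabolic:
    two or more distinct specialized-metabolism families present, or a
    scaffold family together with at least one tailoring family.
    """
    families = [family_map.get(g, "other") for g in group.members]
    cats = [family_category(f) for f in families]
    if sum(c == "kinase" for c in cats) >= kinase_fraction * len(cats):
        return "kinase"
    specialized = {f for f, c in zip(families, cats) if c in ("scaffold", "tailoring")}
    has_scaffold = any(c == "scaffold" for c in cats)
    has_tailoring = any(c == "tailoring" for c in cats)
    if len(specialized) >= 2 or (has_scaffold and has_tailoring):
        return "metabolic"
    return "other"


def classify_groups(
    groups: Sequence[AdjacencyGroup],
    gene_table: GeneTable,
    kinase_fraction: float = 0.5,
) -> list[AdjacencyGroup]:
    """Attach classifications, reading family labels from the annotation."""
    family_map = {r.gene_id: r.family for r in gene_table}
    out = []
    for g in groups:
        cls = classify_group(g, family_map, kinase_fraction=kinase_fraction)
        out.append(
            AdjacencyGroup(
                group_id=g.group_id,
                chromosome=g.chromosome,
                members=g.members,
                modules=g.modules,
                classification=cls,
                max_gap=g.max_gap,
            )
        )
    return out


def call_candidate_bgcs(
    groups: Sequence[AdjacencyGroup],
    gene_table: GeneTable,
    expr: ExpressionMatrix | None = None,
    transform: str = "log2",
) -> list[CandidateBGC]:
    """Call candidate clusters: metabolic groups with a scaffold-forming gene.

    The bait is the scaffold gene with the highest mean expression (on the
    configured transform), ties broken by gene id; without an expression
    matrix the lexicographically first scaffold gene is used.  Metabolic
    groups without a scaffold (e.g. tandem arrays of one tailoring family)
    are not candidates.
    """
    from .induction import apply_transform

    mean_expr: pd.Series | None = None
    if expr is not None:
        mean_expr = apply_transform(expr, transform).mean(axis=1)

    candidates: list[CandidateBGC] = []
    for group in groups:
        if group.classification != "metabolic":
            continue
        scaffolds = [
            g for g in group.members if gene_table[g].family in SCAFFOLD_CLASS
        ]
        if not scaffolds:
            continue
        classes = {SCAFFOLD_CLASS[gene_table[g].family] for g in scaffolds}
        predicted = classes.pop() if len(classes) == 1 else "unknown"
        if mean_expr is not None:
            in_matrix = [g for g in scaffolds if g in mean_expr.index]
            pool = in_matrix or scaffolds
            bait = sorted(pool, key=lambda g: (-mean_expr.get(g, float("-inf")), g))[0]
        else:
            bait = sorted(scaffolds)[0]
        tailoring = tuple(
            sorted(
                {
                    gene_table[g].family
                    for g in group.members
                    if family_category(gene_table[g].family) == "tailoring"
                }
            )
        )
        candidates.append(
            CandidateBGC(
                bgc_id=f"BGC{len(candidates) + 1}({group.chromosome})",
                group=group,
                scaffold_genes=tuple(sorted(scaffolds)),
                tailoring_families=tailoring,
                predicted_class=predicted,
                bait=bait,
            )
        )
    return candidates


def groups_to_frame(groups: Sequence[AdjacencyGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "chromosome": [g.chromosome for g in groups],
            "size": [g.size for g in groups],
            "classification": [g.classification for g in groups],
            "modules": [",".join(g.modules) for g in groups],
            "members": [",".join(g.members) for g in groups],
        }
    )


def candidates_to_frame(candidates: Sequence[CandidateBGC]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bgc_id": [c.bgc_id for c in candidates],
            "chromosome": [c.group.chromosome for c in candidates],
            "predicted_class": [c.predicted_class for c in candidates],
            "bait": [c.bait for c in candidates],
            "scaffold_genes": [",".join(c.scaffold_genes) for c in candidates],
            "tailoring_families": [",".join(c.tailoring_families) for c in candidates],
            "members": [",".join(c.members) for c in candidates],
        }
    )


def candidates_to_bed(
    candidates: Sequence[CandidateBGC], gene_table: GeneTable
) -> pd.DataFrame:
    """Candidate spans as 0-based half-open BED rows."""
    rows = []
    for c in candidates:
        starts = [gene_table[g].start for g in c.members]
        ends = [gene_table[g].end for g in c.members]
        rows.append((c.group.chromosome, min(starts) - 1, max(ends), c.bgc_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


__all__ = [
    "SCAFFOLD_CLASS",
    "TAILORING_PREFIXES",
    "parse_accession",
    "family_category",
    "find_adjacent_groups",
    "classify_group",
    "classify_groups",
    "call_candidate_bgcs",
    "groups_to_frame",
    "candidates_to_frame",
    "candidates_to_bed",
]
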