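"""Synthetic inputs with planted ground truth.

The generators emulate the statistical structure the discovery pipeline
exploits in real data: a chromosomally ordered, accession-indexed gene
annotation carrying planted runs of adjacent specialized-metabolism genes
(candidate BGCs), kinase arrays and single-family decoy tandems; a study-
structured expression compendium in which one coexpression module carries a
pathogen-induction effect; a TF regulatory network wired preferentially into
the planted clusters; GO labels with a defense-term signal on TF targets;
and homoeolog protein triads diverged from a common ancestor by point
substitution.  Every generator is a pure function of its parameters and
seed, and the returned :class:`SimulationTruth` is sufficient to score any
downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BgcscoutError,
    ExpressionMatrix,
    GeneRecord,
    GeneTable,
    ModuleSet,
    RegulatoryNetwork,
    SampleMetadata,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Planted cluster anatomy by product class: one or two scaffold-forming
#: genes plus at least two tailoring genes, 5-7 members in total.
BGC_TEMPLATES: dict[str, list[list[str]]] = {
    "diterpene": [
        ["KSL", "CPS", "CYP99", "CYP99", "UGT"],
        ["KSL", "KSL", "CPS", "CYP99", "CYP99", "UGT"],
        ["KSL", "CPS", "CYP99", "CYP99", "CYP99", "UGT", "UGT"],
    ],
    "triterpene": [
        ["OSC", "HSD", "CYP51", "CYP51", "CYP51"],
        ["OSC", "CYP51", "HSD", "CYP51", "CYP51", "CYP51"],
    ],
    "flavonoid": [
        ["CHS", "CHS", "CYP71", "OMT", "OMT", "OMT", "CHI"],
        ["CHS", "CYP71", "OMT", "OMT", "CHI"],
    ],
}

#: Paper-scale class mix for six planted clusters: three diterpene, two
#: triterpene (a homologous pair), one flavonoid.
DEFAULT_BGC_TYPES = (
    "diterpene",
    "diterpene",
    "diterpene",
    "triterpene",
    "triterpene",
    "flavonoid",
)

DECOY_FAMILIES = ("UGT", "OMT", "CYP71", "CYP72")
TF_FAMILIES = ("TF:WRKY", "TF:bHLH", "TF:NAC", "TF:HSF", "TF:MYB")

#: Background family frequencies, roughly matching family sizes in a large
#: cereal genome (scaffold enzymes are rare; kinases and tailoring families
#: are large; everything else is "other").
BACKGROUND_FAMILY_PROBS = {
    "other": 0.855,
    "kinase": 0.05,
    "CYP71": 0.02,
    "CYP99": 0.005,
    "UGT": 0.02,
    "OMT": 0.01,
    "SDR": 0.005,
    "TF:WRKY": 0.006,
    "TF:bHLH": 0.008,
    "TF:NAC": 0.006,
    "TF:HSF": 0.004,
    "TF:MYB": 0.006,
    "TPS": 0.002,
    "OSC": 0.0005,
    "CHS": 0.0015,
    "CPS": 0.0005,
}


@dataclass(frozen=True)
class PlantedBGC:
    chromosome: str
    members: tuple[str, ...]
    scaffold: str
    bgc_type: str


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset; serializable to JSON."""

    planted_bgcs: list[PlantedBGC] = field(default_factory=list)
    planted_kinase_arrays: list[tuple[str, ...]] = field(default_factory=list)
    planted_decoy_tandems: list[tuple[str, ...]] = field(default_factory=list)
    induced_modules: list[str] = field(default_factory=list)
    shared_tfs: list[str] = field(default_factory=list)
    tf_groups: list[tuple[str, ...]] = field(default_factory=list)
    effect_size: float = 0.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted_bgcs": [
                {
                    "chromosome": b.chromosome,
                    "members": list(b.members),
                    "scaffold": b.scaffold,
                    "bgc_type": b.bgc_type,
                }
                for b in self.planted_bgcs
            ],
            "planted_kinase_arrays": [list(a) for a in self.planted_kinase_arrays],
            "planted_decoy_tandems": [list(a) for a in self.planted_decoy_tandems],
            "induced_modules": self.induced_modules,
            "shared_tfs": self.shared_tfs,
            "tf_groups": [list(g) for g in self.tf_groups],
            "effect_size": self.effect_size,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            planted_bgcs=[
                PlantedBGC(
                    chromosome=b["chromosome"],
                    members=tuple(b["members"]),
                    scaffold=b["scaffold"],
                    bgc_type=b["bgc_type"],
                )
                for b in obj["planted_bgcs"]
            ],
            planted_kinase_arrays=[tuple(a) for a in obj["planted_kinase_arrays"]],
            planted_decoy_tandems=[tuple(a) for a in obj["planted_decoy_tandems"]],
            induced_modules=list(obj["induced_modules"]),
            shared_tfs=list(obj["shared_tfs"]),
            tf_groups=[tuple(g) for g in obj["tf_groups"]],
            effect_size=obj["effect_size"],
            seed=obj["seed"],
        )


def _chromosome_names(n: int) -> list[str]:
    names = []
    i = 1
    while len(names) < n:
        for sub in "ABD":
            names.append(f"{i}{sub}")
            if len(names) == n:
                break
        i += 1
    return names


def _gene_id(chromosome: str, rank: int) -> str:
    # Accession index steps of 100, IWGSC style.
    return f"TraesCS{chromosome}02G{rank * 100:06d}"


def generate_genome(
    n_chromosomes: int = 5,
    genes_per_chromosome: int = 2000,
    n_bgcs: int = 6,
    n_kinase_arrays: int = 4,
    n_decoy_tandems: int = 10,
    seed: int = 0,
    bgc_types: tuple[str, ...] | None = None,
) -> tuple[GeneTable, SimulationTruth]:
    """Simulate an annotated genome with planted gene runs.

    Planted runs (candidate BGCs, kinase arrays, decoy tandem arrays) occupy
    consecutive ranks, never overlap, and are separated by at least three
    background genes so that adjacent plants cannot merge during mining.
    Background genes receive family labels from a fixed frequency table with
    mild tandem correlation (large families occur in local duplicate runs).
    """
    rng = np.random.default_rng(seed)
    if bgc_types is None:
        bgc_types = tuple(DEFAULT_BGC_TYPES[i % len(DEFAULT_BGC_TYPES)] for i in range(n_bgcs))
    if len(bgc_types) != n_bgcs:
        raise BgcscoutError("bgc_types length must equal n_bgcs")

    max_len = 7
    if genes_per_chromosome < 10 * max_len:
        raise BgcscoutError("genes_per_chromosome must be >= 10x the longest planted run")

    chroms = _chromosome_names(n_chromosomes)
    # Planted runs: (kind, families) in placement order.
    runs: list[tuple[str, list[str]]] = []
    for t in bgc_types:
        templates = BGC_TEMPLATES[t]
        runs.append((f"bgc:{t}", list(templates[rng.integers(len(templates))])))
    for _ in range(n_kinase_arrays):
        runs.append(("kinase", ["kinase"] * int(rng.integers(3, 6))))
    for _ in range(n_decoy_tandems):
        fam = DECOY_FAMILIES[rng.integers(len(DECOY_FAMILIES))]
        runs.append(("decoy", [fam] * int(rng.integers(3, 5))))

    # Place runs on chromosomes without overlap, buffer of 3 ranks.
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placements: list[tuple[str, str, int, list[str]]] = []  # kind, chrom, start_rank, fams
    for kind, fams in runs:
        placed = False
        for _ in range(200):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(1, genes_per_chromosome - len(fams) + 1))
            lo, hi = start - 3, start + len(fams) + 2
            if all(hi < a or lo > b for a, b in occupied[chrom]):
                occupied[chrom].append((lo, hi))
                placements.append((kind, chrom, start, fams))
                placed = True
                break
        if not placed:
            raise BgcscoutError("could not place planted runs; chromosomes too crowded")

    planted_family: dict[tuple[str, int], tuple[str, str]] = {}
    for kind, chrom, start, fams in placements:
        for offset, fam in enumerate(fams):
            planted_family[(chrom, start + offset)] = (kind, fam)

    bg_families = list(BACKGROUND_FAMILY_PROBS)
    bg_probs = np.array(list(BACKGROUND_FAMILY_PROBS.values()))
    bg_probs = bg_probs / bg_probs.sum()
    tandem_prone = {"kinase", "CYP71", "UGT", "OMT"} | set(TF_FAMILIES)

    records: list[GeneRecord] = []
    for chrom in chroms:
        carry: str | None = None
        pos = 1
        for rank in range(1, genes_per_chromosome + 1):
            key = (chrom, rank)
            if key in planted_family:
                fam = planted_family[key][1]
                carry = None
            elif carry is not None:
                fam = carry
                carry = None if rng.random() > 0.3 else carry
            else:
                fam = bg_families[rng.choice(len(bg_families), p=bg_probs)]
                if fam in tandem_prone and rng.random() < 0.25:
                    carry = fam
            length = int(rng.integers(1000, 8000))
            records.append(
                GeneRecord(
                    gene_id=_gene_id(chrom, rank),
                    chromosome=chrom,
                    start=pos,
                    end=pos + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    family=fam,
                    numeric_index=rank * 100,
                )
            )
            pos += length + int(rng.integers(500, 5000))

    table = GeneTable(records)
    truth = SimulationTruth(seed=seed)
    for kind, chrom, start, fams in placements:
        members = tuple(_gene_id(chrom, start + i) for i in range(len(fams)))
        if kind.startswith("bgc:"):
            bgc_type = kind.split(":", 1)[1]
            scaffold_fams = {"diterpene": {"KSL", "CPS", "TPS"}, "triterpene": {"OSC"}, "flavonoid": {"CHS"}}[bgc_type]
            scaffold = next(m for m, f in zip(members, fams) if f in scaffold_fams)
            truth.planted_bgcs.append(
                PlantedBGC(chromosome=chrom, members=members, scaffold=scaffold, bgc_type=bgc_type)
            )
        elif kind == "kinase":
            truth.planted_kinase_arrays.append(members)
        else:
            truth.planted_decoy_tandems.append(members)
    return table, truth


def generate_expression(
    genome: GeneTable,
    truth: SimulationTruth,
    n_studies: int = 7,
    samples_per_arm: int = 6,
    effect_size: float = 3.0,
    within_module_cor: float = 0.8,
    noise_sd: float = 1.0,
    n_modules: int = 40,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleMetadata, ModuleSet]:
    """Simulate the expression compendium, study design and module map.

    Log2-scale Gaussian model: gene g in sample s has
    ``mu_g + sqrt(rho) * f_{m(g),s} + sqrt(1-rho) * noise_sd * eps_{g,s}``
    (f a per-module shared factor, eps gene-level noise, rho =
    ``within_module_cor``), plus ``effect_size`` when s is a treatment
    sample and g's module is the induced one; values are mapped to a
    TPM-like scale as ``2**x - 1`` clipped at zero.  At ``noise_sd = 1``
    the within-module correlation is exactly rho; at ``noise_sd = 0``
    module genes have identical profiles up to their baselines.  All planted runs (clusters, kinase arrays, decoys) are
    assigned to the single induced module; background genes are assigned
    uniformly over all modules.  ``effect_size`` is in log2 units, which for
    ``noise_sd = 1`` is approximately eigengene z-units.
    """
    if effect_size < 0:
        raise BgcscoutError("effect_size must be >= 0")
    if not 0.0 <= within_module_cor <= 1.0:
        raise BgcscoutError("within_module_cor must be in [0, 1]")
    rng = np.random.default_rng(seed)

    module_ids = [f"ME{i}" for i in range(1, n_modules + 1)]
    induced_module = "ME25" if n_modules >= 25 else module_ids[0]

    planted_genes: list[str] = []
    for b in truth.planted_bgcs:
        planted_genes.extend(b.members)
    for arr in truth.planted_kinase_arrays:
        planted_genes.extend(arr)
    for arr in truth.planted_decoy_tandems:
        planted_genes.extend(arr)
    planted_set = set(planted_genes)

    genes = genome.gene_ids
    assignment: dict[str, str] = {}
    for g in genes:
        if g in planted_set:
            assignment[g] = induced_module
        else:
            assignment[g] = module_ids[rng.integers(n_modules)]
    modules = ModuleSet(assignment=assignment)
    truth.induced_modules = [induced_module]
    truth.effect_size = effect_size

    rows = []
    sample_ids: list[str] = []
    treated: list[bool] = []
    for s in range(1, n_studies + 1):
        for arm, flag in (("t", True), ("c", False)):
            for i in range(1, samples_per_arm + 1):
                sample_ids.append(f"study{s}_{arm}{i}")
                treated.append(flag)
                rows.append(
                    {
                        "sample_id": f"study{s}_{arm}{i}",
                        "study_id": f"study{s}",
                        "condition": "treatment" if flag else "control",
                        "stress_class": "biotic" if flag else "none",
                        "tissue": "leaf",
                    }
                )
    meta = SampleMetadata(table=pd.DataFrame(rows))
    n_samples = len(sample_ids)
    treated_arr = np.array(treated, dtype=float)

    module_index = {m: i for i, m in enumerate(module_ids)}
    gene_module = np.array([module_index[assignment[g]] for g in genes])
    mu = rng.uniform(2.0, 9.0, size=len(genes))
    factors = rng.standard_normal((n_modules, n_samples))
    eps = rng.standard_normal((len(genes), n_samples))
    rho = within_module_cor
    log2 = (
        mu[:, None]
        + np.sqrt(rho) * factors[gene_module, :]
        + np.sqrt(1.0 - rho) * noise_sd * eps
    )
    induced_mask = gene_module == module_index[induced_module]
    log2[induced_mask, :] += effect_size * treated_arr[None, :]
    tpm = np.clip(np.exp2(log2) - 1.0, 0.0, None)

    expr = ExpressionMatrix(values=pd.DataFrame(tpm, index=genes, columns=sample_ids))
    return expr, meta, modules


def generate_network(
    genome: GeneTable,
    truth: SimulationTruth,
    n_shared_tfs: int = 21,
    tfs_per_bgc: int = 5,
    background_edges: int = 2000,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Simulate a GENIE3-style TF->target network wired to the planted clusters.

    ``n_shared_tfs`` TF-family genes get at least one edge into every planted
    cluster (the paper-style shared regulators); each cluster additionally
    receives edges from ``tfs_per_bgc`` cluster-specific TFs; background
    edges land uniformly on non-cluster genes.  Shared-TF tandem structure
    (same family within five ranks on a chromosome) is recorded in
    ``truth.tf_groups``.
    """
    rng = np.random.default_rng(seed)
    tf_pool = sorted(
        r.gene_id for r in genome if r.family.startswith("TF:")
    )
    need = n_shared_tfs + tfs_per_bgc * len(truth.planted_bgcs)
    if need > len(tf_pool):
        raise BgcscoutError(f"not enough TF-family genes ({len(tf_pool)}) for request")
    chosen = list(rng.choice(len(tf_pool), size=need, replace=False)) if need else []
    shared = [tf_pool[i] for i in chosen[:n_shared_tfs]]
    specific = [tf_pool[i] for i in chosen[n_shared_tfs:]]

    bgc_members = [list(b.members) for b in truth.planted_bgcs]
    cluster_gene_set = {g for mem in bgc_members for g in mem}
    edges: list[tuple[str, str, float]] = []
    for tf in shared:
        for members in bgc_members:
            n_hits = 1 + int(rng.integers(0, 3))
            for idx in rng.choice(len(members), size=min(n_hits, len(members)), replace=False):
                edges.append((tf, members[idx], float(rng.uniform(0.5, 1.0))))
    for tf in specific:
        if not bgc_members:
            break
        # partial regulators: hit a proper subset of the planted clusters
        k = int(rng.integers(1, len(bgc_members))) if len(bgc_members) > 1 else 1
        for ci in rng.choice(len(bgc_members), size=k, replace=False):
            members = bgc_members[ci]
            for idx in rng.choice(len(members), size=min(2, len(members)), replace=False):
                edges.append((tf, members[idx], float(rng.uniform(0.3, 1.0))))

    non_cluster = [g for g in genome.gene_ids if g not in cluster_gene_set]
    all_tfs = shared + specific if (shared or specific) else tf_pool
    for _ in range(background_edges):
        if not all_tfs:
            break
        tf = all_tfs[rng.integers(len(all_tfs))]
        target = non_cluster[rng.integers(len(non_cluster))]
        if target != tf:
            edges.append((tf, target, float(rng.uniform(0.0, 0.5))))

    truth.shared_tfs = sorted(shared)
    truth.tf_groups = _tandem_groups(sorted(shared), genome, window=5)
    frame = pd.DataFrame(edges, columns=["tf", "target", "weight"])
    if frame.empty:
        frame = pd.DataFrame(columns=["tf", "target", "weight"])
    return RegulatoryNetwork(edges=frame)


def _tandem_groups(tf_ids: list[str], genome: GeneTable, window: int) -> list[tuple[str, ...]]:
    """Connected components of the same-chromosome/same-family/nearby relation."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(tf_ids)
    recs = [genome[t] for t in tf_ids]
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            if (
                a.chromosome == b.chromosome
                and a.family == b.family
                and abs(a.rank - b.rank) <= window
            ):
                g.add_edge(a.gene_id, b.gene_id)
    return sorted(tuple(sorted(c)) for c in nx.connected_components(g))


def generate_go_annotation(
    genome: GeneTable,
    network: RegulatoryNetwork,
    truth: SimulationTruth,
    n_background_terms: int = 30,
    defense_term: str = "GO:0006952",
    seed: int = 0,
) -> dict[str, set[str]]:
    """Simulate a flat gene -> GO term map with a planted defense signal.

    Targets of the shared TFs carry the defense-response term with high
    probability; background genes rarely do.  Background terms are assigned
    uniformly (one to three per gene).
    """
    rng = np.random.default_rng(seed)
    shared_targets: set[str] = set()
    for tf in truth.shared_tfs:
        shared_targets |= network.targets_of(tf)
    terms = [f"GO:{7000000 + i}" for i in range(n_background_terms)]
    annotation: dict[str, set[str]] = {}
    for g in genome.gene_ids:
        k = 1 + int(rng.integers(0, 3))
        chosen = {terms[i] for i in rng.choice(len(terms), size=k, replace=False)}
        p_def = 0.6 if g in shared_targets else 0.03
        if rng.random() < p_def:
            chosen.add(defense_term)
        annotation[g] = chosen
    return annotation


def generate_proteins(
    triad_structure: list[tuple[str, ...]] | int = 10,
    length: int = 700,
    mutation_rate: float = 0.005,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], list[dict[str, str]]]:
    """Simulate homoeolog protein sets diverged from common ancestors.

    ``triad_structure`` is either a count (complete A/B/D triads) or a list
    of subgenome tuples, e.g. ``[("A","B","D"), ("A","D")]`` to emulate a
    B-genome absence.  Each member derives from a uniform-random ancestor by
    independent per-site substitution (probability ``mutation_rate``, uniform
    over the 19 alternative residues), so the expected pairwise identity
    between members is ``(1 - mutation_rate)**2``.

    Returns ``(sets, truth)`` where ``sets`` maps subgenome -> {name: seq}
    and ``truth`` lists each family's member names by subgenome.
    """
    if not 0.0 <= mutation_rate < 1.0:
        raise BgcscoutError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(triad_structure, int):
        triad_structure = [("A", "B", "D")] * triad_structure
    subgenomes = sorted({s for tup in triad_structure for s in tup})
    sets: dict[str, dict[str, str]] = {s: {} for s in subgenomes}
    truth: list[dict[str, str]] = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for i, tup in enumerate(triad_structure, start=1):
        ancestor = aa[rng.integers(len(aa), size=length)]
        entry: dict[str, str] = {}
        for sub in tup:
            seq = ancestor.copy()
            hits = rng.random(length) < mutation_rate
            for j in np.nonzero(hits)[0]:
                alternatives = aa[aa != seq[j]]
                seq[j] = alternatives[rng.integers(len(alternatives))]
            name = f"fam{i}_{sub}"
            sets[sub][name] = seq.tobytes().decode()
            entry[sub] = name
        truth.append(entry)
    return sets, truth


def score_candidates(candidates, truth: SimulationTruth) -> dict[str, float]:
    """Precision/recall of called candidate clusters against the planted truth.

    A candidate matches a planted cluster when its member set contains all
    planted members (mining may legitimately extend a run by a boundary gene
    that happens to fall in a selected module).  Precision counts matching
    candidates; recall counts distinct planted clusters recovered.
    """
    planted = [set(b.members) for b in truth.planted_bgcs]
    matched_candidates = 0
    recovered: set[int] = set()
    for cand in candidates:
        members = set(cand.members)
        for i, p in enumerate(planted):
            if p <= members:
                matched_candidates += 1
                recovered.add(i)
                break
    n_cand = len(list(candidates))
    return {
        "n_candidates": float(n_cand),
        "n_planted": float(len(planted)),
        "precision": matched_candidates / n_cand if n_cand else float("nan"),
        "recall": len(recovered) / len(planted) if planted else float("nan"),
    }
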