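"""Core domain types for coexpression-guided biosynthetic gene cluster mining.

The types here mirror the objects that flow through the discovery pipeline:
an ordered, chromosome-assigned gene annotation (:class:`GeneTable`), a
TPM-like expression compendium with its study design (:class:`ExpressionMatrix`,
:class:`SampleMetadata`), a precomputed coexpression module assignment
(:class:`ModuleSet`), and a directed transcription-factor regulatory network
(:class:`RegulatoryNetwork`).  Downstream result types (adjacency groups,
candidate clusters, coexpression reports, enrichment rows, alignments) are
lightweight frozen records.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default accession pattern: IWGSC-style wheat ids such as "TraesCS2B02G445900"
#: (prefix + chromosome token + assembly version + "G" + numeric index).
#: Any pattern with named groups ``chromosome`` and ``index`` may be substituted.
DEFAULT_ACCESSION_PATTERN = re.compile(
    r"^[A-Za-z]+CS(?P<chromosome>\d{1,2}[A-Z]|U)\d{2}G(?P<index>\d+)$"
)

VALID_STRANDS = {"+", "-"}
VALID_CONDITIONS = {"treatment", "control"}
VALID_STRESS_CLASSES = {"biotic", "abiotic", "none"}


class BgcscoutError(ValueError):
    """Base class for domain validation errors."""


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene.

    ``numeric_index`` is parsed from the accession when the id matches the
    configured pattern; ``rank`` is the 1-based ordinal position of the gene
    on its chromosome after sorting by numeric index (or by file order for
    genomes without numeric accessions).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    family: str = "other"
    numeric_index: int | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise BgcscoutError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise BgcscoutError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GeneTable:
    """Ordered collection of :class:`GeneRecord` with per-chromosome ranks.

    Ranks are assigned at construction: within each chromosome, genes are
    sorted by ``numeric_index`` when every record on that chromosome carries
    one, otherwise input order is kept, and ranks run 1..n.  Construction is
    therefore invariant to input shuffling for accession-indexed genomes.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        records = list(records)
        ids = [r.gene_id for r in records]
        dup = [g for g, c in Counter(ids).items() if c > 1]
        if dup:
            raise BgcscoutError(f"duplicate gene ids: {sorted(dup)[:5]}")
        by_chrom: dict[str, list[GeneRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chromosome, []).append(rec)
        ranked: list[GeneRecord] = []
        for chrom in sorted(by_chrom):
            group = by_chrom[chrom]
            if all(r.numeric_index is not None for r in group):
                group = sorted(group, key=lambda r: (r.numeric_index, r.gene_id))
            for i, rec in enumerate(group, start=1):
                ranked.append(replace(rec, rank=i))
        self._records: tuple[GeneRecord, ...] = tuple(ranked)
        self._by_id: dict[str, GeneRecord] = {r.gene_id: r for r in ranked}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self._records]

    @property
    def chromosomes(self) -> list[str]:
        return sorted({r.chromosome for r in self._records})

    def on_chromosome(self, chromosome: str) -> list[GeneRecord]:
        """Genes on one chromosome, in rank order."""
        return [r for r in self._records if r.chromosome == chromosome]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self._records],
                "chromosome": [r.chromosome for r in self._records],
                "start": [r.start for r in self._records],
                "end": [r.end for r in self._records],
                "strand": [r.strand for r in self._records],
                "family": [r.family for r in self._records],
                "numeric_index": [r.numeric_index for r in self._records],
                "rank": [r.rank for r in self._records],
            }
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative TPM-like values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise BgcscoutError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise BgcscoutError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise BgcscoutError("non-finite expression values")
        if (arr < 0).any():
            raise BgcscoutError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, gene_id: str) -> pd.Series:
        return self.values.loc[gene_id]


@dataclass
class SampleMetadata:
    """Study design of the compendium: one row per sample.

    Columns: sample_id, study_id, condition (treatment/control),
    stress_class (biotic/abiotic/none), tissue.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "study_id", "condition", "stress_class", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise BgcscoutError(f"metadata missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise BgcscoutError("duplicate sample ids in metadata")
        bad = set(self.table["condition"]) - VALID_CONDITIONS
        if bad:
            raise BgcscoutError(f"bad condition values: {sorted(bad)}")
        bad = set(self.table["stress_class"]) - VALID_STRESS_CLASSES
        if bad:
            raise BgcscoutError(f"bad stress_class values: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def study_ids(self) -> list[str]:
        return sorted(self.table["study_id"].unique())

    def samples_of(self, study_id: str, condition: str | None = None) -> list[str]:
        t = self.table[self.table["study_id"] == study_id]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["sample_id"])

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Every matrix sample must have exactly one metadata row."""
        known = set(self.table["sample_id"])
        orphans = [s for s in expr.samples if s not in known]
        if orphans:
            raise BgcscoutError(f"samples without metadata: {orphans[:5]}")


@dataclass
class ModuleSet:
    """Coexpression module assignment (gene -> module id), e.g. from WGCNA."""

    assignment: dict[str, str]

    @property
    def module_ids(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def genes_in(self, module_id: str) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m == module_id)

    def genes_in_any(self, module_ids: Iterable[str]) -> set[str]:
        wanted = set(module_ids)
        return {g for g, m in self.assignment.items() if m in wanted}


@dataclass(frozen=True)
class EigengeneProfile:
    """Per-module representative expression profile (per-sample mean)."""

    module_id: str
    values: pd.Series  # index: sample ids
    normalized: bool = False


@dataclass(frozen=True)
class InductionScore:
    """Treatment-minus-control induction of a module eigengene, per study."""

    module_id: str
    per_study_delta: Mapping[str, float]
    mean_delta: float
    rank: int | None = None


class RegulatoryNetwork:
    """Directed, weighted TF -> target edge list (GENIE3-style, consumed as given).

    Duplicated edges keep the maximum weight; self-loops are dropped since
    they never count toward cluster incidence.
    """

    def __init__(self, edges: pd.DataFrame):
        required = {"tf", "target", "weight"}
        missing = required - set(edges.columns)
        if missing:
            raise BgcscoutError(f"edge table missing columns: {sorted(missing)}")
        if (edges["weight"].to_numpy() < 0).any():
            raise BgcscoutError("negative edge weights")
        edges = edges[edges["tf"] != edges["target"]]
        edges = (
            edges.groupby(["tf", "target"], as_index=False)["weight"]
            .max()
            .sort_values(["tf", "target"])
            .reset_index(drop=True)
        )
        self.edges = edges

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def targets_of(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])


@dataclass(frozen=True)
class AdjacencyGroup:
    """A maximal run of physically adjacent genes from the selected modules."""

    group_id: str
    chromosome: str
    members: tuple[str, ...]  # gene ids in rank order
    modules: tuple[str, ...]
    classification: str | None = None  # kinase / metabolic / other
    max_gap: int = 1

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CandidateBGC:
    """A metabolic adjacency group with at least one scaffold-forming gene."""

    bgc_id: str
    group: AdjacencyGroup
    scaffold_genes: tuple[str, ...]
    tailoring_families: tuple[str, ...]
    predicted_class: str  # diterpene / triterpene / flavonoid / unknown
    bait: str | None = None

    @property
    def members(self) -> tuple[str, ...]:
        return self.group.members


@dataclass(frozen=True)
class CoexpressionReport:
    """Pearson r of every cluster member against the scaffold bait gene."""

    bgc_id: str
    bait: str
    r: pd.Series  # index: member gene ids; NaN marks undefined (zero variance)
    flags: pd.Series  # boolean, r strictly greater than threshold
    n_samples: int
    threshold: float


@dataclass(frozen=True)
class TFBGCSummary:
    """Per-TF incidence over candidate clusters (clusters hit, not edges)."""

    tf: str
    bgcs: frozenset[str]
    group_id: str | None = None

    @property
    def incidence(self) -> int:
        return len(self.bgcs)


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's hypergeometric enrichment in a gene selection."""

    term: str
    k: int  # selected genes carrying the term
    K: int  # background genes carrying the term
    n: int  # selection size
    N: int  # background size
    p: float  # upper-tail hypergeometric probability P(X >= k)
    q: float  # Benjamini-Hochberg adjusted p


@dataclass(frozen=True)
class AlignmentResult:
    """Global pairwise protein alignment summary."""

    query: str
    subject: str
    score: float
    aligned_length: int
    n_identical: int
    n_similar: int
    percent_identity: float
    percent_similarity: float
    gap_mode: str = "exclude_terminal"


@dataclass(frozen=True)
class SyntenyBlock:
    """A chain of ortholog anchors monotone in gene order on both genomes."""

    anchors: tuple[tuple[str, str], ...]
    chromosome_a: str
    chromosome_b: str
    orientation: str  # collinear / inverted

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def parse_accession(
    gene_id: str,
    pattern: re.Pattern[str] | str = DEFAULT_ACCESSION_PATTERN,
    lenient: bool = False,
) -> tuple[str, int] | None:
    """Extract (chromosome token, numeric index) from an accession-style id.

    >>> parse_accession("TraesCS2B02G445900")
    ('2B', 445900)

    Unassigned-scaffold genes use chromosome token "U".  Non-matching ids
    raise unless ``lenient`` is set, in which case ``None`` is returned.
    """
    if isinstance(pattern, str):
        pattern = re.compile(pattern)
    m = pattern.match(gene_id)
    if m is None:
        if lenient:
            return None
        raise BgcscoutError(f"gene id {gene_id!r} does not match accession pattern")
    return m.group("chromosome"), int(m.group("index"))
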