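"""Protein homology and microsynteny utilities.

Global pairwise alignment uses the Needleman-Wunsch-Gotoh algorithm (via
Biopython's PairwiseAligner) with BLOSUM62 and affine gaps (open 10, extend
0.5), exact rather than heuristic — appropriate at the scale of candidate
cluster protein sets.  "Similarity" follows the BlastP positives convention:
the fraction of aligned columns with a positive substitution score.  Percent
identity is computed over the alignment length excluding terminal gaps by
default (configurable), since published identity values rarely state a
convention.

Orthology is reciprocal-best-hit (RBH) by alignment score; homoeolog triads
are built from pairwise-consistent RBH triangles across subgenome protein
sets, and incomplete triads (dyads/singletons) are how subgenome absence is
detected.  Microsynteny blocks are maximal chains of ortholog anchors
monotone in gene (rank) order on both genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .types import AlignmentResult, BgcscoutError, SyntenyBlock

log = logging.getLogger("bgcscout")


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    """Global affine-gap protein aligner; unknown residue X scores zero."""
    m = substitution_matrices.load(matrix).copy()
    if "X" in m.alphabet:
        for c in m.alphabet:
            m["X", c] = 0.0
            m[c, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    query: str = "query",
    subject: str = "subject",
    aligner: Align.PairwiseAligner | None = None,
    gap_mode: str = "exclude_terminal",
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences with column stats.

    Among co-optimal alignments the aligner's canonical first traceback is
    reported, which is deterministic for fixed inputs and parameters.
    """
    if not a or not b:
        raise BgcscoutError("empty sequence")
    if gap_mode not in ("exclude_terminal", "full"):
        raise BgcscoutError(f"unknown gap_mode {gap_mode!r}")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix

    n_cols = len(sa)
    first = max(_first_residue(sa), _first_residue(sb))
    last = min(_last_residue(sa), _last_residue(sb))
    n_ident = 0
    n_sim = 0
    for ca, cb in zip(sa[first : last + 1], sb[first : last + 1]):
        if ca == "-" or cb == "-":
            continue
        if matrix is not None:
            score = matrix[ca, cb]
        else:  # simple match/mismatch aligner
            score = aligner.match_score if ca == cb else aligner.mismatch_score
        if ca == cb:
            n_ident += 1
            n_sim += 1
        elif score > 0:
            n_sim += 1
    denom = (last - first + 1) if gap_mode == "exclude_terminal" else n_cols
    return AlignmentResult(
        query=query,
        subject=subject,
        score=float(alignment.score),
        aligned_length=last - first + 1,
        n_identical=n_ident,
        n_similar=n_sim,
        percent_identity=100.0 * n_ident / denom,
        percent_similarity=100.0 * n_sim / denom,
        gap_mode=gap_mode,
    )


def _first_residue(s: str) -> int:
    return len(s) - len(s.lstrip("-"))


def _last_residue(s: str) -> int:
    return len(s.rstrip("-")) - 1


def _best_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    aligner: Align.PairwiseAligner,
) -> dict[str, str | None]:
    """Unique best-scoring subject per query (None on a tied best)."""
    best: dict[str, str | None] = {}
    for qname, qseq in queries.items():
        scores = {sname: aligner.score(qseq, sseq) for sname, sseq in subjects.items()}
        top = max(scores.values())
        winners = sorted(s for s, sc in scores.items() if sc == top)
        if len(winners) != 1:
            log.info("tied best hit for %s: %s", qname, winners)
            best[qname] = None
        else:
            best[qname] = winners[0]
    return best


def rbh_pairs(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = 0.0,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs between two protein sets.

    (a, b) is reported iff b is a's unique best hit and a is b's unique best
    hit; ties yield no pair.  ``min_identity`` (percent) optionally drops
    low-identity reciprocal pairs, which is how absent true orthologs are
    kept from matching a random best hit.
    """
    if not set_a or not set_b:
        raise BgcscoutError("both protein sets must be non-empty")
    if aligner is None:
        aligner = make_aligner()
    a_best = _best_hits(set_a, set_b, aligner)
    b_best = _best_hits(set_b, set_a, aligner)
    pairs = []
    for a_name, b_name in sorted(a_best.items()):
        if b_name is not None and b_best.get(b_name) == a_name:
            if min_identity > 0.0:
                res = global_align(set_a[a_name], set_b[b_name], aligner=aligner)
                if res.percent_identity < min_identity:
                    continue
            pairs.append((a_name, b_name))
    return pairs


@dataclass(frozen=True)
class TriadAssignment:
    """Homoeolog family call across subgenomes.

    status: "triad" (one member per subgenome, all pairwise RBH edges agree),
    "dyad" (two subgenomes linked; the third absent), "singleton", or
    "inconsistent" (RBH edges do not form a clean family).
    """

    members: tuple[tuple[str, str], ...]  # (subgenome, protein name)
    status: str
    missing: tuple[str, ...] = ()


def assign_triads(
    sets: Mapping[str, Mapping[str, str]],
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = 0.0,
) -> list[TriadAssignment]:
    """Build homoeolog triads from pairwise RBH consistency.

    ``sets`` maps subgenome label (e.g. "A", "B", "D") to its protein set.
    A complete triad requires mutually consistent RBH pairs between every
    pair of subgenomes; dyads and singletons report which subgenomes lack a
    member — this is how subgenome-specific cluster absence shows up.
    """
    import networkx as nx

    if aligner is None:
        aligner = make_aligner()
    subgenomes = sorted(sets)
    g = nx.Graph()
    for sub in subgenomes:
        for name in sets[sub]:
            g.add_node((sub, name))
    for i, sa in enumerate(subgenomes):
        for sb in subgenomes[i + 1 :]:
            if not sets[sa] or not sets[sb]:
                continue
            for a_name, b_name in rbh_pairs(sets[sa], sets[sb], aligner, min_identity):
                g.add_edge((sa, a_name), (sb, b_name))

    out: list[TriadAssignment] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        subs = [s for s, _ in comp]
        present = sorted(set(subs))
        missing = tuple(s for s in subgenomes if s not in present)
        if len(comp) == 1:
            status = "singleton"
        elif len(subs) != len(present):
            status = "inconsistent"  # two members from one subgenome
        elif len(comp) == len(subgenomes) and g.subgraph(comp).number_of_edges() == len(
            subgenomes
        ) * (len(subgenomes) - 1) // 2:
            status = "triad"
        elif len(comp) == 2:
            status = "dyad"
        else:
            status = "inconsistent"
        out.append(TriadAssignment(members=tuple(comp), status=status, missing=missing))
    out.sort(key=lambda t: t.members)
    return out


@dataclass(frozen=True)
class Anchor:
    """An ortholog pair with gene-order coordinates on both genomes."""

    gene_a: str
    gene_b: str
    chromosome_a: str
    chromosome_b: str
    rank_a: int
    rank_b: int


def synteny_blocks(
    anchors: Sequence[Anchor],
    min_anchors: int = 3,
    max_rank_gap: int = 10,
) -> list[SyntenyBlock]:
    """Maximal chains of anchors monotone in rank on both genomes.

    Within a chromosome pair, chains are strictly increasing in genome-A
    rank and strictly monotone (increasing = collinear, decreasing =
    inverted) in genome-B rank, with per-step rank gaps of at most
    ``max_rank_gap`` on both genomes.  The longest chain is extracted
    first (ties: collinear orientation, then earliest start), its anchors
    removed, and the search repeated while chains of ``min_anchors`` remain.
    """
    blocks: list[SyntenyBlock] = []
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chromosome_a, a.chromosome_b), []).append(a)
    for (ca, cb), group in sorted(by_pair.items()):
        remaining = sorted(group, key=lambda a: (a.rank_a, a.rank_b))
        while True:
            best_chain, best_orient = None, None
            for orient in ("collinear", "inverted"):
                chain = _longest_chain(remaining, orient, max_rank_gap)
                if best_chain is None or len(chain) > len(best_chain):
                    best_chain, best_orient = chain, orient
            if best_chain is None or len(best_chain) < min_anchors:
                break
            blocks.append(
                SyntenyBlock(
                    anchors=tuple((a.gene_a, a.gene_b) for a in best_chain),
                    chromosome_a=ca,
                    chromosome_b=cb,
                    orientation=best_orient,
                )
            )
            used = {(a.gene_a, a.gene_b) for a in best_chain}
            remaining = [a for a in remaining if (a.gene_a, a.gene_b) not in used]
    return blocks


def _longest_chain(
    anchors: Sequence[Anchor], orientation: str, max_rank_gap: int
) -> list[Anchor]:
    """O(n^2) DP for the longest qualifying chain; deterministic tie-breaks."""
    n = len(anchors)
    if n == 0:
        return []
    sign = 1 if orientation == "collinear" else -1
    length = [1] * n
    parent = [-1] * n
    for i in range(n):
        for j in range(i):
            da = anchors[i].rank_a - anchors[j].rank_a
            db = sign * (anchors[i].rank_b - anchors[j].rank_b)
            if 1 <= da <= max_rank_gap and 1 <= db <= max_rank_gap:
                if length[j] + 1 > length[i]:
                    length[i] = length[j] + 1
                    parent[i] = j
    best = int(np.argmax(length))  # argmax takes the earliest on ties
    chain = []
    while best != -1:
        chain.append(anchors[best])
        best = parent[best]
    return chain[::-1]


def alignments_to_frame(results: Sequence[AlignmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": [r.query for r in results],
            "subject": [r.subject for r in results],
            "score": [r.score for r in results],
            "aligned_length": [r.aligned_length for r in results],
            "percent_identity": [r.percent_identity for r in results],
            "percent_similarity": [r.percent_similarity for r in results],
        }
    )


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome_a": [b.chromosome_a for b in blocks],
            "chromosome_b": [b.chromosome_b for b in blocks],
            "orientation": [b.orientation for b in blocks],
            "n_anchors": [b.n_anchors for b in blocks],
            "anchors": [";".join(f"{x}|{y}" for x, y in b.anchors) for b in blocks],
        }
    )
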