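"""Regulatory-network overlay on candidate clusters and GO enrichment.

Per-TF incidence counts how many candidate clusters a transcription factor
has at least one predicted edge into (clusters, not edges; self-loops never
count).  TFs are merged into groups of homoeologs and/or tandem duplicates,
and shared regulators are those hitting at least ``min_bgcs`` clusters.  GO
enrichment of TF target sets uses the upper-tail hypergeometric test with
Benjamini-Hochberg correction; annotation is taken as-is with no ontology
propagation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import (
    BgcscoutError,
    CandidateBGC,
    EnrichmentResult,
    GeneTable,
    RegulatoryNetwork,
    TFBGCSummary,
)


def tf_bgc_incidence(
    network: RegulatoryNetwork, candidates: Sequence[CandidateBGC]
) -> list[TFBGCSummary]:
    """One summary per TF with at least one edge into any candidate member."""
    member_of: dict[str, str] = {}
    for cand in candidates:
        for g in cand.members:
            member_of[g] = cand.bgc_id
    hits: dict[str, set[str]] = {}
    for tf, target in zip(network.edges["tf"], network.edges["target"]):
        bgc = member_of.get(target)
        if bgc is not None:
            hits.setdefault(tf, set()).add(bgc)
    return [
        TFBGCSummary(tf=tf, bgcs=frozenset(bgcs)) for tf, bgcs in sorted(hits.items())
    ]


def group_tfs(
    tf_ids: Iterable[str],
    gene_table: GeneTable,
    triads: Sequence[Mapping[str, str]] | None = None,
    tandem_window: int = 5,
) -> list[tuple[str, ...]]:
    """Merge TFs into homoeolog/tandem groups (connected components).

    Two TFs are related if they belong to the same homoeolog triad (when
    triad assignments are supplied) or are tandem duplicates: same
    chromosome, same family, within ``tandem_window`` ranks.
    """
    tf_ids = sorted(set(tf_ids))
    g = nx.Graph()
    g.add_nodes_from(tf_ids)
    recs = [gene_table[t] for t in tf_ids if t in gene_table]
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            if (
                a.chromosome == b.chromosome
                and a.family == b.family
                and abs(a.rank - b.rank) <= tandem_window
            ):
                g.add_edge(a.gene_id, b.gene_id)
    if triads:
        tf_set = set(tf_ids)
        for triad in triads:
            members = [m for m in triad.values() if m in tf_set]
            for i in range(len(members) - 1):
                g.add_edge(members[i], members[i + 1])
    return sorted(tuple(sorted(c)) for c in nx.connected_components(g))


def attach_groups(
    summaries: Sequence[TFBGCSummary], groups: Sequence[tuple[str, ...]]
) -> list[TFBGCSummary]:
    group_of = {tf: f"TFG{i:03d}" for i, grp in enumerate(groups, 1) for tf in grp}
    return [
        TFBGCSummary(tf=s.tf, bgcs=s.bgcs, group_id=group_of.get(s.tf)) for s in summaries
    ]


def count_shared_tfs(
    summaries: Sequence[TFBGCSummary], min_bgcs: int
) -> tuple[int, int]:
    """(number of TFs, number of TF groups) with incidence >= min_bgcs."""
    if min_bgcs < 1:
        raise BgcscoutError("min_bgcs must be >= 1")
    shared = [s for s in summaries if s.incidence >= min_bgcs]
    groups = {s.group_id if s.group_id is not None else s.tf for s in shared}
    return len(shared), len(groups)


def go_enrichment(
    selection: Iterable[str],
    annotation: Mapping[str, set[str]],
    background: Iterable[str],
    report_zero: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric GO enrichment with BH correction.

    For each term with at least one selected gene (all terms if
    ``report_zero``): p = P(X >= k) for X ~ Hypergeom(N, K, n), where N is
    the background size (unannotated genes count toward N with zero terms),
    K the background genes carrying the term, n the selection size and k
    the selected genes carrying it.  Results sort by q, then p, then term.
    """
    selection = set(selection)
    background = set(background)
    if not selection:
        raise BgcscoutError("empty selection")
    if not selection <= background:
        raise BgcscoutError("selection must be a subset of the background")
    term_bg: dict[str, int] = {}
    term_sel: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):  # genes without terms still count in N
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in selection:
                term_sel[term] = term_sel.get(term, 0) + 1
    N, n = len(background), len(selection)
    terms = sorted(term_bg if report_zero else term_sel)
    if not terms:
        return []
    pvals = []
    for term in terms:
        k = term_sel.get(term, 0)
        K = term_bg[term]
        pvals.append(float(hypergeom.sf(k - 1, N, K, n)))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term=term,
            k=term_sel.get(term, 0),
            K=term_bg[term],
            n=n,
            N=N,
            p=p,
            q=float(q),
        )
        for term, p, q in zip(terms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def summaries_to_frame(summaries: Sequence[TFBGCSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tf": [s.tf for s in summaries],
            "incidence": [s.incidence for s in summaries],
            "group_id": [s.group_id for s in summaries],
            "bgcs": [",".join(sorted(s.bgcs)) for s in summaries],
        }
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
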