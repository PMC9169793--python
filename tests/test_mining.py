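"""Adjacency mining, run classification and candidate cluster calling."""

import numpy as np
import pandas as pd
import pytest

from bgcscout.mining import (
    call_candidate_bgcs,
    classify_group,
    classify_groups,
    find_adjacent_groups,
)
from bgcscout.simulate import generate_genome, score_candidates
from bgcscout.types import AdjacencyGroup, ExpressionMatrix, GeneRecord, GeneTable

from conftest import make_gene_table


def brute_force_runs(ranks, min_size, max_gap):
    """Oracle: enumerate all maximal runs of sorted ranks with gaps <= max_gap."""
    ranks = sorted(ranks)
    runs, current = [], []
    for r in ranks:
        if current and r - current[-1] > max_gap:
            runs.append(current)
            current = []
        current.append(r)
    if current:
        runs.append(current)
    return [tuple(run) for run in runs if len(run) >= min_size]


def table_with_ranks(n=30, chrom="1A"):
    return make_gene_table([(f"g{i}", chrom, i * 100) for i in range(1, n + 1)])


class TestFindAdjacentGroups:
    def test_single_run_among_scattered_members(self):
        table = table_with_ranks()
        members = {f"g{i}" for i in (5, 6, 7, 20, 21)}
        groups = find_adjacent_groups(table, members, min_size=3, max_gap=1)
        assert len(groups) == 1
        assert groups[0].members == ("g5", "g6", "g7")

    def test_five_consecutive_accessions_form_one_group(self):
        # mirrors a five-gene block of successive accessions on an
        # unassigned scaffold
        table = make_gene_table(
            [(f"TraesCSU02G{8700 + i * 100:06d}", "U", 8700 + i * 100) for i in range(5)]
        )
        groups = find_adjacent_groups(table, set(table.gene_ids))
        assert len(groups) == 1
        assert groups[0].size == 5

    def test_empty_module_set(self):
        assert find_adjacent_groups(table_with_ranks(), set()) == []

    def test_gap_tolerance(self):
        table = table_with_ranks()
        members = {"g1", "g3", "g5", "g7"}
        assert find_adjacent_groups(table, members, max_gap=1) == []
        groups = find_adjacent_groups(table, members, max_gap=2)
        assert len(groups) == 1 and groups[0].size == 4

    @pytest.mark.parametrize("max_gap", [1, 2, 3])
    def test_matches_bruteforce_oracle_on_random_instances(self, max_gap):
        rng = np.random.default_rng(100 + max_gap)
        for _ in range(60):
            n = int(rng.integers(10, 200))
            table = make_gene_table(
                [(f"g{c}_{i}", c, i * 100) for c in ("1A", "2B") for i in range(1, n + 1)]
            )
            members = {
                f"g{c}_{i}"
                for c in ("1A", "2B")
                for i in range(1, n + 1)
                if rng.random() < 0.3
            }
            got = find_adjacent_groups(table, members, min_size=3, max_gap=max_gap)
            for chrom in ("1A", "2B"):
                ranks = sorted(
                    int(g.split("_")[1]) for g in members if g.startswith(f"g{chrom}")
                )
                expected = brute_force_runs(ranks, 3, max_gap)
                found = [
                    tuple(int(m.split("_")[1]) for m in grp.members)
                    for grp in got
                    if grp.chromosome == chrom
                ]
                assert found == expected

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        spec = [(f"g{i}", "1A", i * 100) for i in range(1, 40)]
        members = {f"g{i}" for i in rng.choice(range(1, 40), 15, replace=False)}
        shuffled = list(spec)
        rng.shuffle(shuffled)
        g1 = find_adjacent_groups(make_gene_table(spec), members)
        g2 = find_adjacent_groups(make_gene_table(shuffled), members)
        assert [g.members for g in g1] == [g.members for g in g2]

    def test_no_overlapping_groups(self, small_dataset):
        genome, _, _, _, modules, _ = small_dataset
        groups = find_adjacent_groups(genome, set(genome.gene_ids), max_gap=2)
        for chrom in genome.chromosomes:
            spans = [
                (genome[g.members[0]].rank, genome[g.members[-1]].rank)
                for g in groups
                if g.chromosome == chrom
            ]
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 < a2


def group_of(families):
    return AdjacencyGroup(
        group_id="G", chromosome="1A",
        members=tuple(f"g{i}" for i in range(len(families))), modules=(),
    ), {f"g{i}": fam for i, fam in enumerate(families)}


class TestClassification:
    def test_all_kinase(self):
        g, fams = group_of(["kinase"] * 4)
        assert classify_group(g, fams) == "kinase"

    def test_flavonoid_cluster_content(self):
        # CHS scaffold with CYP71, OMTs and a chalcone-flavanone isomerase
        g, fams = group_of(["CHS", "CHS", "CYP71", "OMT", "OMT", "OMT", "CHI"])
        assert classify_group(g, fams) == "metabolic"

    def test_triterpene_cluster_content(self):
        g, fams = group_of(["OSC", "HSD", "CYP51", "CYP51", "CYP51"])
        assert classify_group(g, fams) == "metabolic"

    def test_single_family_tandem_is_other(self):
        g, fams = group_of(["UGT", "UGT", "UGT"])
        assert classify_group(g, fams) == "other"

    def test_partition_property(self, small_dataset):
        genome, _, _, _, modules, _ = small_dataset
        groups = find_adjacent_groups(genome, modules.genes_in_any(["ME25"]), modules=modules)
        groups = classify_groups(groups, genome)
        counts = {
            c: sum(g.classification == c for g in groups)
            for c in ("kinase", "metabolic", "other")
        }
        assert sum(counts.values()) == len(groups)


class TestCandidateCalling:
    def make_genome_and_groups(self, families):
        table = make_gene_table([(f"g{i}", "5D", (i + 1) * 100) for i in range(len(families))])
        records = [
            GeneRecord(
                gene_id=f"g{i}", chromosome="5D", start=1 + i * 10, end=5 + i * 10,
                strand="+", family=fam, numeric_index=(i + 1) * 100,
            )
            for i, fam in enumerate(families)
        ]
        table = GeneTable(records)
        groups = find_adjacent_groups(table, set(table.gene_ids))
        return table, classify_groups(groups, table)

    def test_no_metabolic_groups_gives_empty_list(self):
        table, groups = self.make_genome_and_groups(["kinase"] * 4)
        assert call_candidate_bgcs(groups, table) == []

    def test_scaffoldless_metabolic_group_excluded(self):
        table, groups = self.make_genome_and_groups(["UGT", "UGT", "UGT"])
        assert groups[0].classification == "other"
        assert call_candidate_bgcs(groups, table) == []

    def test_flavonoid_class_prediction(self):
        table, groups = self.make_genome_and_groups(
            ["CHS", "CHS", "CYP71", "OMT", "OMT", "OMT", "CHI"]
        )
        cands = call_candidate_bgcs(groups, table)
        assert len(cands) == 1
        assert cands[0].predicted_class == "flavonoid"

    def test_bait_is_highest_expressed_scaffold(self):
        table, groups = self.make_genome_and_groups(["OSC", "OSC", "CYP51", "HSD", "CYP51"])
        expr = ExpressionMatrix(
            values=pd.DataFrame(
                {"s0": [1.0, 50.0, 2.0, 2.0, 2.0], "s1": [2.0, 60.0, 2.0, 2.0, 2.0]},
                index=[f"g{i}" for i in range(5)],
            )
        )
        cands = call_candidate_bgcs(groups, table, expr=expr)
        assert cands[0].bait == "g1"
        # without expression: lexicographically first scaffold
        assert call_candidate_bgcs(groups, table)[0].bait == "g0"

    def test_planted_genome_recovers_exactly_the_planted_clusters(self):
        genome, truth = generate_genome(seed=21)
        planted = {g for b in truth.planted_bgcs for g in b.members}
        planted |= {g for a in truth.planted_kinase_arrays for g in a}
        planted |= {g for a in truth.planted_decoy_tandems for g in a}
        groups = classify_groups(find_adjacent_groups(genome, planted), genome)
        cands = call_candidate_bgcs(groups, genome)
        score = score_candidates(cands, truth)
        assert score["precision"] == 1.0 and score["recall"] == 1.0
        got = {c.predicted_class for c in cands}
        assert got == {b.bgc_type for b in truth.planted_bgcs}
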