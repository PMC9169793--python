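"""Full discovery run on a simulated wheat-like dataset with planted clusters.

Generates a 5-chromosome genome carrying six planted biosynthetic gene
clusters (plus kinase arrays and decoy tandem duplications), a 7-study
treatment/control expression compendium in which one coexpression module is
pathogen-induced, and a TF network wired to the planted clusters — then runs
every pipeline stage and scores the calls against the planted truth.
"""

from bgcscout.pipeline import discover
from bgcscout.simulate import (
    generate_expression,
    generate_genome,
    generate_go_annotation,
    generate_network,
    score_candidates,
)

genome, truth = generate_genome(seed=42)
expr, meta, modules = generate_expression(genome, truth, seed=10_042)
network = generate_network(genome, truth, n_shared_tfs=21, seed=20_042)
go = generate_go_annotation(genome, network, truth, seed=30_042)

report = discover(genome, expr, meta, modules, network=network, go_annotation=go)

print(f"top modules by induction: {report.top_modules}")
print(f"rank-1 module mean delta (z-units): {report.scores[0].mean_delta:.3f}")
print(f"adjacency groups mined: {report.summary['n_adjacency_groups']} "
      f"({report.summary['n_kinase_groups']} kinase, "
      f"{report.summary['n_metabolic_groups']} metabolic)")
print(f"candidate clusters called: {report.summary['n_candidate_bgcs']} "
      f"{report.summary['candidate_classes']}")
score = score_candidates(report.candidates, truth)
print(f"vs planted truth: precision {score['precision']:.2f}, recall {score['recall']:.2f}")
print(f"TFs hitting every candidate cluster: {report.n_shared_tfs} "
      f"in {report.n_shared_tf_groups} homoeolog/tandem groups")
if report.enrichment:
    top = report.enrichment[0]
    print(f"top enriched GO term in shared-TF targets: {top.term} "
          f"(k={top.k}/{top.n}, q={top.q:.2e})")
# A rank-1 induced module, six candidates at precision/recall 1.0 and the
# planted defense term at the top of the enrichment table mean every stage
# recovered the structure the simulation planted.
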