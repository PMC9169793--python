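import numpy as np
import pandas as pd
import pytest

from bgcscout.simulate import (
    generate_expression,
    generate_genome,
    generate_network,
)
from bgcscout.types import (
    ExpressionMatrix,
    GeneRecord,
    GeneTable,
    ModuleSet,
    SampleMetadata,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by module-level tests."""
    genome, truth = generate_genome(
        n_chromosomes=3,
        genes_per_chromosome=300,
        n_bgcs=3,
        n_kinase_arrays=2,
        n_decoy_tandems=3,
        seed=7,
    )
    expr, meta, modules = generate_expression(
        genome, truth, n_studies=4, samples_per_arm=4, effect_size=3.0,
        n_modules=12, seed=8,
    )
    network = generate_network(
        genome, truth, n_shared_tfs=5, tfs_per_bgc=2, background_edges=300, seed=9
    )
    return genome, truth, expr, meta, modules, network


def make_gene_table(spec):
    """Build a GeneTable from (gene_id, chromosome, index) triples; genes are
    laid out with non-overlapping coordinates in input order."""
    records = []
    for i, (gene_id, chrom, idx) in enumerate(spec):
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chromosome=chrom,
                start=1 + i * 10_000,
                end=5_000 + i * 10_000,
                strand="+",
                family="other",
                numeric_index=idx,
            )
        )
    return GeneTable(records)


def make_expression(values: dict[str, list[float]], samples=None) -> ExpressionMatrix:
    frame = pd.DataFrame(values).T
    if samples is not None:
        frame.columns = samples
    else:
        frame.columns = [f"s{i}" for i in range(frame.shape[1])]
    return ExpressionMatrix(values=frame)


def make_metadata(rows) -> SampleMetadata:
    return SampleMetadata(
        table=pd.DataFrame(
            rows, columns=["sample_id", "study_id", "condition", "stress_class", "tissue"]
        )
    )
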