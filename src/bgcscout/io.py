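"""Readers and writers for the external formats the pipeline consumes.

Annotation comes in either as a 6-column TSV (gene_id, chromosome, start,
end, strand, family) or as GFF3 gene features (parsed with gffutils, family
taken from the ``family=`` attribute).  Expression, metadata, module maps,
edge lists and GO maps are plain TSV; proteins are FASTA via Biopython.
"""

from __future__ import annotations

import json
import logging
import re
import tempfile
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    DEFAULT_ACCESSION_PATTERN,
    BgcscoutError,
    ExpressionMatrix,
    GeneRecord,
    GeneTable,
    ModuleSet,
    RegulatoryNetwork,
    SampleMetadata,
    parse_accession,
)

log = logging.getLogger("bgcscout")

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "family"]


def _records_from_rows(
    rows: list[dict], pattern: re.Pattern[str] | str
) -> list[GeneRecord]:
    records = []
    skipped = 0
    for row in rows:
        chrom = row.get("chromosome")
        if chrom is None or (isinstance(chrom, float) and pd.isna(chrom)) or chrom == "":
            log.warning("skipping %s: missing chromosome", row.get("gene_id"))
            skipped += 1
            continue
        parsed = parse_accession(str(row["gene_id"]), pattern=pattern, lenient=True)
        numeric_index = parsed[1] if parsed is not None else None
        records.append(
            GeneRecord(
                gene_id=str(row["gene_id"]),
                chromosome=str(chrom),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                family=str(row.get("family", "other")),
                numeric_index=numeric_index,
            )
        )
    if skipped:
        log.warning("skipped %d annotation records", skipped)
    return records


def read_gene_annotation(
    path: str | Path, pattern: re.Pattern[str] | str = DEFAULT_ACCESSION_PATTERN
) -> GeneTable:
    """Read a gene annotation from TSV or GFF3 and assign chromosome ranks.

    Ids matching the accession pattern get numeric indices (rank = sorted
    index order per chromosome); otherwise file order within each chromosome
    is used as the rank order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        rows = _rows_from_gff3(path)
    else:
        table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        missing = set(ANNOTATION_COLUMNS) - set(table.columns)
        if missing:
            raise BgcscoutError(f"annotation missing columns: {sorted(missing)}")
        rows = table.to_dict("records")
    return GeneTable(_records_from_rows(rows, pattern))


def _rows_from_gff3(path: Path) -> list[dict]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        family = feat.attributes.get("family", ["other"])[0]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chromosome": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
                "family": family,
            }
        )
    return rows


def write_gene_annotation(table: GeneTable, path: str | Path) -> None:
    frame = table.to_frame()[ANNOTATION_COLUMNS]
    frame.to_csv(path, sep="\t", index=False)


def write_gff3(table: GeneTable, path: str | Path, source: str = "bgcscout") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in table:
            attrs = f"ID={rec.gene_id};family={rec.family}"
            fh.write(
                f"{rec.chromosome}\t{source}\tgene\t{rec.start}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\t{attrs}\n"
            )


def read_expression(
    matrix_path: str | Path, metadata_path: str | Path
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read the expression compendium and its study design, cross-validated.

    The matrix TSV has gene ids in the first column and sample ids in the
    header; any matrix sample missing from the metadata is an error naming
    the sample.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    expr = ExpressionMatrix(values=values)
    meta = SampleMetadata(table=pd.read_csv(metadata_path, sep="\t", dtype=str))
    meta.validate_against(expr)
    return expr, meta


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_module_map(path: str | Path) -> ModuleSet:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "module_id"} <= set(table.columns):
        raise BgcscoutError("module map needs columns gene_id, module_id")
    if table["gene_id"].duplicated().any():
        raise BgcscoutError("gene assigned to more than one module")
    return ModuleSet(assignment=dict(zip(table["gene_id"], table["module_id"])))


def write_module_map(modules: ModuleSet, path: str | Path) -> None:
    pd.DataFrame(
        sorted(modules.assignment.items()), columns=["gene_id", "module_id"]
    ).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> RegulatoryNetwork:
    table = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    return RegulatoryNetwork(edges=table)


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_go_annotation(path: str | Path) -> dict[str, set[str]]:
    """Flat gene -> GO term table (one row per gene/term pair)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term"} <= set(table.columns):
        raise BgcscoutError("GO map needs columns gene_id, term")
    out: dict[str, set[str]] = {}
    for gene, term in zip(table["gene_id"], table["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_go_annotation(annotation: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(annotation) for t in sorted(annotation[g])]
    pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def format_float(x: float) -> str:
    """Fixed report formatting: 6 significant digits."""
    return f"{x:.6g}"


def write_report_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report TSV with floats at 6 significant digits."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
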