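"""Readers and writers for the pipeline's plain-text formats.

Formats: long-format time-course TSV, DEG tables (TSV), gene sets (GMT),
backgrounds (one id per line), alignments (BED6+2 with coverage and
identity in the two extra columns), annotations (BED6 or GFF3 gene
features) and transcript→gene mapping tables.  GFF3 coordinates (1-based
inclusive) are converted to the package's 0-based half-open convention at
this single site.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd

from .enrich import GeneSet, GeneSetCollection
from .idmap import AlignmentRecord, GeneModel, GenomeInterval, IdMapping

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_background",
    "write_background",
    "read_alignments_bed",
    "write_alignments_bed",
    "read_annotation",
    "write_annotation_gff3",
    "write_annotation_bed",
    "write_mapping_tsv",
]

BED_ALIGNMENT_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand", "coverage", "identity",
]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, source/description, tab-separated members."""
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT lines need name, source and members"
                )
            name, source, *members = parts
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, source=source, members=members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.source, *gs.members]) + "\n")


def read_background(path) -> set[str]:
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip()}
    if not ids:
        raise ValueError(f"background file {path} is empty")
    return ids


def write_background(ids, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(gid + "\n")


def read_alignments_bed(path) -> list[AlignmentRecord]:
    """Read transcript alignments from BED6+2 (extra columns: coverage,
    identity)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_ALIGNMENT_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AlignmentRecord(
                transcript_id=str(row.name),
                interval=GenomeInterval(
                    chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                    strand=str(row.strand),
                ),
                coverage=float(row.coverage),
                identity=float(row.identity),
            )
        )
    return records


def write_alignments_bed(records: list[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.transcript_id}\t0\t"
                f"{iv.strand}\t{r.coverage:.6f}\t{r.identity:.6f}\n"
            )


def read_annotation(path) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features) or BED6.

    Dispatch is by file extension (.gff/.gff3 versus anything else, read
    as BED).  GFF3 starts are shifted by −1 to 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True,
            merge_strategy="error", from_string=False,
        )
        genes = []
        for feat in db.features_of_type("gene"):
            genes.append(
                GeneModel(
                    gene_id=feat.id,
                    interval=GenomeInterval(
                        chrom=feat.seqid, start=feat.start - 1, end=feat.end,
                        strand=feat.strand if feat.strand in "+-" else ".",
                    ),
                )
            )
        return genes
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        GeneModel(
            gene_id=str(row.name),
            interval=GenomeInterval(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                strand=str(row.strand),
            ),
        )
        for row in df.itertuples(index=False)
    ]


def write_annotation_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.chrom}\tstemstat\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={g.gene_id}\n"
            )


def write_annotation_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n"
            )


def write_mapping_tsv(mapping: IdMapping, path) -> None:
    """Write the transcript → gene table with a status column."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tstatus\n")
        for tid in sorted(mapping.assignments):
            fh.write(f"{tid}\t{mapping.assignments[tid]}\tassigned\n")
        for tid in sorted(mapping.dropped_ambiguous):
            fh.write(f"{tid}\t.\tambiguous\n")
        for tid in sorted(mapping.dropped_filtered):
            fh.write(f"{tid}\t.\tfiltered\n")
        for tid in sorted(mapping.unassigned):
            fh.write(f"{tid}\t.\tunassigned\n")
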