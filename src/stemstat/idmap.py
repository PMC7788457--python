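"""Cross-assembly gene-set harmonization by filtered interval alignment.

Published gene sets for the same organism are frequently defined on
different transcriptome assemblies.  To compare them with a new analysis,
each assembly's transcripts are aligned to a common genome, alignments are
filtered by coverage and identity, and each surviving transcript is
assigned to the annotation gene it overlaps *reciprocally* (shared length
at least a fraction f of both intervals, f = 0.5 by default).  Transcripts
that reciprocally overlap more than one gene are ambiguous and dropped
entirely; published sets are then translated through the resulting
transcript → gene mapping into the analysis gene space.

Coordinates are 0-based half-open throughout; GFF3 input is converted at
a single site in :mod:`stemstat.io`.  Strand is ignored in overlap tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .enrich import GeneSet

__all__ = [
    "GenomeInterval",
    "AlignmentRecord",
    "GeneModel",
    "IdMapping",
    "normalize_transcript_id",
    "filter_alignments",
    "reciprocal_overlap",
    "assign_transcripts",
    "build_mapping",
    "map_gene_set",
]

# default isoform appendix: a final underscore plus digits
DEFAULT_SUFFIX_PATTERN = r"_\d+$"


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """One transcript alignment with its coverage and identity fractions."""

    transcript_id: str
    interval: GenomeInterval
    coverage: float
    identity: float

    def __post_init__(self) -> None:
        for name, v in (("coverage", self.coverage), ("identity", self.identity)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomeInterval


@dataclass
class IdMapping:
    """Transcript → gene assignment with its discard bookkeeping.

    ``assignments`` maps each uniquely assignable transcript to exactly one
    gene; ``dropped_ambiguous`` lists transcripts with more than one
    candidate gene; ``dropped_filtered`` lists transcripts removed by the
    coverage/identity filter; ``unassigned`` lists filtered-in transcripts
    overlapping no gene reciprocally.
    """

    assignments: dict[str, str] = field(default_factory=dict)
    dropped_ambiguous: list[str] = field(default_factory=list)
    dropped_filtered: list[str] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.assignments) & (
            set(self.dropped_ambiguous) | set(self.dropped_filtered)
        )
        if overlap:
            raise ValueError(f"transcripts both assigned and dropped: {overlap}")

    @property
    def assigned_genes(self) -> set[str]:
        return set(self.assignments.values())


def normalize_transcript_id(
    id: str, suffix_pattern: str = DEFAULT_SUFFIX_PATTERN
) -> str:
    """Strip one trailing isoform appendix from a transcript id.

    The default pattern removes a final underscore-plus-digits suffix, e.g.
    ``dd_Smed_v6_1234_0_1 → dd_Smed_v6_1234_0``; non-matching ids pass
    through unchanged.  Exactly one trailing occurrence is removed per
    call.
    """
    if not id:
        raise ValueError("transcript id must be nonempty")
    return re.sub(suffix_pattern, "", id, count=1)


def filter_alignments(
    records: list[AlignmentRecord],
    min_coverage: float = 0.9,
    min_identity: float = 0.9,
) -> list[AlignmentRecord]:
    """Keep alignments with coverage and identity at or above the cutoffs
    (inclusive, matching the "min-" semantics of aligner thresholds)."""
    for name, v in (("min_coverage", min_coverage), ("min_identity", min_identity)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return [
        r for r in records
        if r.coverage >= min_coverage and r.identity >= min_identity
    ]


def reciprocal_overlap(
    a: GenomeInterval, b: GenomeInterval, fraction: float = 0.5
) -> bool:
    """True when the intervals share >= ``fraction`` of *each* length.

    Requires the same chromosome and a strictly positive overlap; strand is
    ignored.  Symmetric in its two interval arguments.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if a.chrom != b.chrom:
        return False
    o = min(a.end, b.end) - max(a.start, b.start)
    if o <= 0:
        return False
    return o / len(a) >= fraction and o / len(b) >= fraction


def _overlap_length(a: GenomeInterval, b: GenomeInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _gene_index(annotation: list[GeneModel]) -> dict[str, IntervalTree]:
    seen: set[str] = set()
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id in annotation: {g.gene_id!r}")
        seen.add(g.gene_id)
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    return trees


def assign_transcripts(
    alignments: list[AlignmentRecord],
    annotation: list[GeneModel],
    fraction: float = 0.5,
    keep_best: bool = False,
) -> IdMapping:
    """Assign transcripts to genes by reciprocal interval overlap.

    Candidate genes for a transcript are all annotation genes passing
    :func:`reciprocal_overlap` with any of the transcript's alignment
    records.  Exactly one candidate → assigned; several candidates →
    ``dropped_ambiguous`` (unless ``keep_best``, which keeps the candidate
    with the largest overlap length and drops exact ties); none →
    ``unassigned``.  The result does not depend on input order.
    """
    trees = _gene_index(annotation)
    candidates: dict[str, dict[str, int]] = {}
    for rec in alignments:
        cand = candidates.setdefault(rec.transcript_id, {})
        tree = trees.get(rec.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(rec.interval.start, rec.interval.end):
            gene: GeneModel = hit.data
            if reciprocal_overlap(rec.interval, gene.interval, fraction):
                o = _overlap_length(rec.interval, gene.interval)
                prev = cand.get(gene.gene_id, 0)
                cand[gene.gene_id] = max(prev, o)
    mapping = IdMapping()
    for tid in sorted(candidates):
        cand = candidates[tid]
        if len(cand) == 0:
            mapping.unassigned.append(tid)
        elif len(cand) == 1:
            mapping.assignments[tid] = next(iter(cand))
        elif keep_best:
            best = max(cand.values())
            winners = [g for g, o in cand.items() if o == best]
            if len(winners) == 1:
                mapping.assignments[tid] = winners[0]
            else:
                mapping.dropped_ambiguous.append(tid)
        else:
            mapping.dropped_ambiguous.append(tid)
    return mapping


def build_mapping(
    records: list[AlignmentRecord],
    annotation: list[GeneModel],
    min_coverage: float = 0.9,
    min_identity: float = 0.9,
    fraction: float = 0.5,
    keep_best: bool = False,
) -> IdMapping:
    """Filter alignments, assign transcripts and record every discard.

    A transcript lands in ``dropped_filtered`` only when *all* of its
    alignment records fail the coverage/identity filter.
    """
    kept = filter_alignments(records, min_coverage, min_identity)
    kept_ids = {r.transcript_id for r in kept}
    all_ids = {r.transcript_id for r in records}
    mapping = assign_transcripts(kept, annotation, fraction, keep_best)
    mapping.dropped_filtered = sorted(all_ids - kept_ids)
    return mapping


def map_gene_set(
    set_ids: list[str],
    mapping: IdMapping,
    name: str = "mapped",
    source: str = "idmap",
    suffix_pattern: str | None = None,
) -> tuple[GeneSet | None, list[str]]:
    """Translate published transcript ids into the analysis gene space.

    Each id (after optional isoform-appendix normalization) is looked up
    in ``mapping.assignments``; unmatched ids are returned separately.
    Mapped gene ids are de-duplicated.  Returns ``(None, unmapped)`` when
    no id maps.
    """
    mapped: dict[str, None] = {}
    unmapped: list[str] = []
    for raw in set_ids:
        tid = (
            normalize_transcript_id(raw, suffix_pattern)
            if suffix_pattern is not None
            else raw
        )
        gene = mapping.assignments.get(tid)
        if gene is None:
            unmapped.append(raw)
        else:
            mapped.setdefault(gene, None)
    if not mapped:
        return None, unmapped
    return GeneSet(name=name, source=source, members=list(mapped)), unmapped
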