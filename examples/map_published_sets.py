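"""Translate a published transcript-level gene set into an analysis gene space.

Generates a toy genome with 100 genes and 100 transcript alignments in
which 80 transcripts map uniquely, 10 straddle two genes (ambiguous) and
10 fail the coverage/identity filter, then maps a published set of
transcript ids (carrying isoform appendices) onto annotation genes.
"""

from stemstat import build_mapping, map_gene_set
from stemstat.simgen import gen_genome_fixture

genes, alignments, published, truth = gen_genome_fixture(seed=13)

mapping = build_mapping(
    alignments, genes, min_coverage=0.9, min_identity=0.9, fraction=0.5
)
print(f"assigned uniquely: {len(mapping.assignments)}")
print(f"dropped (ambiguous, >1 candidate gene): {len(mapping.dropped_ambiguous)}")
print(f"dropped (sub-threshold coverage/identity): {len(mapping.dropped_filtered)}")

pub = published[0]
mapped, unmapped = map_gene_set(pub.members, mapping, suffix_pattern=r"_\d+$")
print(f"published set: {len(pub.members)} transcript ids "
      f"-> {len(mapped.members)} genes, {len(unmapped)} unmapped")
print("matches planted truth:",
      sorted(mapped.members) == truth["expected_mapped_genes"])

# The unmapped ids belong to transcripts that were either ambiguous or
# filtered out — exactly the ids the mapping deliberately discards.
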