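"""Build a junction-extended reference for a small annotated genome.

Constructs a toy genome with one three-exon transcript, builds the
extension for 50 bp reads, and prints where each junction-spanning
sequence landed and which genomic blocks it concatenates.
"""

import numpy as np

from splicelift import (
    ExonInterval,
    TranscriptModel,
    build_extended_reference,
    flank_length,
)

rng = np.random.default_rng(0)
genome = {"chr1": "".join(rng.choice(list("ACGT"), size=10_000))}

tx = TranscriptModel(
    transcript_id="T1", gene_id="G1", chrom="chr1", strand="+",
    exons=[
        ExonInterval("chr1", 100, 900),
        ExonInterval("chr1", 2000, 2010),   # 10 bp exon, shorter than the flank
        ExonInterval("chr1", 5000, 5800),
    ],
).validate()

read_length = 50
ref = build_extended_reference(genome, [tx], read_length=read_length)

print(f"flank for {read_length} bp reads: {flank_length(read_length)} bases")
print(f"extended chr1 length: {len(ref.sequences['chr1'])} "
      f"(genomic {ref.original_lengths['chr1']})")
for rec in ref.records:
    blocks = ",".join(f"{b.start}-{b.end}" for b in rec.blocks)
    print(f"{rec.junction_id}: ext_start={rec.ext_start} length={rec.length} "
          f"blocks={blocks}")

# The second junction's left flank (49 bases) cannot fit in the 10-base
# middle exon, so its sequence concatenates three genomic blocks: a read
# aligned across it will span all three exons.
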