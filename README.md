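# splicelift

Annotation-based spliced alignment of RNA-seq reads via a junction-extended
reference, for pipelines built around ungapped short-read aligners such as
BWA.

RNA-seq reads frequently span exon–exon junctions, so they cannot be placed
on the genome by an aligner that does not model introns. Instead of teaching
the aligner to splice, `splicelift` extends the reference: for every
annotated junction it appends a *junction-spanning sequence* — up to
`flank = L − m` exonic bases on each side of the splice boundary, where `L`
is the read length and `m ≥ 1` a minimum overhang — after the end of the
junction's chromosome. When a neighbouring exon is shorter than the flank,
the sequence continues into the next exon of the same transcript, so one
read may span several exons. Because every junction sequence block is
shorter than `L`, no unspliced read can align wholly inside the junction
portion; conversely any junction-crossing read aligns there contiguously.

After alignment against this extended reference, the companion *junction
map* (the ordered genomic block list of every junction sequence) is used to
translate junction-region alignments back to genomic coordinates:

- match/deletion CIGAR runs are split at every block boundary and an `N`
  operator of exactly the intron length `block[i+1].start − block[i].end`
  is inserted, turning an ungapped `100M` into e.g. `97M942N3M`;
- POS is projected through the block list; SEQ, QUAL and strand are
  untouched;
- mate fields (RNEXT/PNEXT/TLEN) and the proper-pair FLAG bit are
  recomputed from the translated genomic coordinates;
- MAPQ values zeroed only because a locus occurs in both the genomic and
  the junction portion of the extended reference are restored once every
  alternative hit translates onto the primary alignment.

Novel (unannotated) junctions are out of scope by design: the method sees
only the junctions present in the annotation.

## Usage

```
splicelift build-reference --genome genome.fa --gtf models.gtf \
    --read-length 100 --out-fasta extended.fa --out-map extended.jmap
# index extended.fa with your aligner and align reads against it, then:
splicelift translate --map extended.jmap --in aligned.bam \
    --out genomic.bam --summary summary.tsv
```

The extension must be rebuilt for each read length. `translate` refuses to
run when the SAM/BAM header does not match the map, and
`--expect-read-length` guards against using a map built for different
reads.

## Worked example

`examples/translate_alignments.py` builds a seeded synthetic scenario
(two 50 kb chromosomes, 30 transcripts, 1000 reads of 100 bp), constructs
the extended reference, places the reads on it, and translates them back:

```
30 transcripts, 130 junction sequences, 1000 reads

example translation (read000001):
  extended:  chr2:53376 100M
  genomic:   chr2:5825 97M942N3M

category counts: {'junction_translated': 436, 'genomic_passthrough': 564}
junction reads matching the exon-walk oracle: 436/436
```

The read aligned ungapped at position 53,376 of the extended chr2 — inside
a junction sequence — and translates to a spliced genomic alignment at
5,825 whose `942N` gap is the intron between the two exons it spans.
Every one of the 436 junction-region alignments projects, base by base, to
exactly the coordinates of an independent oracle that walks the
originating transcript's exon chain. `examples/build_reference.py` and
`examples/pair_and_mapq_repair.py` demonstrate multi-exon junction
sequences and the pair/MAPQ repair rules in the same style.

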