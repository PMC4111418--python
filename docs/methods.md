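# Methods

## The protocol

`splicelift` implements an annotation-based route to spliced RNA-seq
alignment. The aligner itself stays splice-unaware; all splice knowledge
lives in the reference and in a post-alignment coordinate translation.

**Reference construction.** From a genome FASTA and transcript models
(exon features of a GTF), every adjacent exon pair of every transcript
defines an exon–exon junction, identified by its splice-site pair
`(chrom, donor_end, acceptor_start)` with transcript ids kept as
provenance. For each junction and each supporting transcript a
*junction-spanning sequence* is assembled on the genomic forward strand:
walk backward from the donor end through the transcript's exon chain
accumulating up to `flank` bases, walk forward from the acceptor start
likewise, and concatenate the visited genomic blocks in ascending order.
Short exons are crossed, so a junction sequence may contain three or more
blocks; flanks truncate silently at transcript termini. Block lists
identical in `(chrom, block tuple)` are emitted once; the same splice
boundary reached through different short-exon neighbourhoods yields
separate sequences, because they project differently. Junction sequences
are appended after the chromosome's genomic sequence, each preceded by a
spacer of `N`s, in deterministic order (chrom, donor, acceptor, block
tuple). The block lists, offsets and build parameters are persisted as a
tab-delimited *junction map*.

**Translation.** An alignment whose reference span lies within the
original chromosome passes through byte-identical. One contained in a
junction sequence is projected back: reference-consuming runs (`M`, `D`,
`=`, `X`, and any incoming `N`) are split wherever they cross — or sit on
either side of — a block boundary, with an `N` of exactly the intron
length inserted; query-only operators (`I`, `S`, `H`) attach to the
preceding block's output; adjacent equal operators are re-merged, and an
`N` can never end up terminal. POS becomes the projection of the first
reference-consuming offset. Alignments touching spacer padding or
straddling region boundaries are aligner artifacts: they are set unmapped
with an `XJ:Z:spacer` tag and counted, rather than aborting the run.

**Pair and MAPQ repair.** Pairing is re-judged in genomic coordinates:
RNEXT/PNEXT come from the mate's translated position, TLEN is the genomic
span (rightmost reference end − leftmost start, positive on the leftmost
mate), and the proper-pair bit requires both mates mapped on one
chromosome in FR orientation within `max_span`. Alternative-hit tags
(`XA`) are decoded, each hit translated, and hits whose translated
`(rname, pos, strand, cigar)` equal the primary's are discarded as the
same locus seen through the junction copy; when a MAPQ-0 record loses all
its alternatives this way it was unique after all and receives
`restored_mapq`. Undecodable tags pass through untouched with a warning.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `read_length` | required | read size the extension is built for (rebuild per size) |
| `min_overhang` | 1 | minimum bases a full-length read must cross the boundary by; `flank = read_length − min_overhang` |
| `spacer` | `read_length` | `N` padding before each junction sequence |
| `restored_mapq` | 60 | MAPQ assigned when all alternatives collapse onto the primary |
| `max_span` | 1,000,000 | genomic span ceiling for the proper-pair bit |

The flank formula is the minimal choice that makes every read-length
window of a fully flanked junction sequence cross the splice boundary, so
unspliced reads cannot align to the junction portion; larger `min_overhang`
trades junction sensitivity at the boundary for fewer marginal overhangs.
A spacer of one read length guarantees no alignment can bridge two
unrelated junction sequences or the genome/junction boundary without
touching `N`s. MAPQ 60 is the conventional unique-alignment ceiling of the
BWA family; since the duplication introduced by the extension is exactly
what zeroed these qualities, restoring a definite "unique" value is the
honest inverse. The proper-pair span threshold cannot reuse the aligner's
insert-size model — translated pairs legitimately span introns — so a
generous genomic ceiling is exposed as a parameter instead.

## Numerical and representational choices

Internal coordinates are 0-based half-open everywhere; GTF is read as
1-based inclusive and SAM POS written 1-based, both conversions bijective.
Junction sequences are built on the genomic forward strand regardless of
transcript strand (alignment is strand-symmetric; reverse-strand
transcripts' reads simply align as reverse complements), which halves the
reference and keeps projection arithmetic strand-free. Insertions or
clips falling exactly on a block boundary attach to the left block — a
deterministic tie-break consistent with leftmost-alignment conventions.
Deletions crossing a boundary split like matches with the `N` between the
pieces, preserving total deleted length and keeping `N` purely intronic.
Abutting exon pairs within a transcript (zero-length introns) carry no
junction and are skipped with a warning; blocks that touch after a flank
walk are merged so every inter-block gap is a real intron. Mate pairing
in the stream buffers primary records by read name, so input order is
irrelevant; secondary and supplementary records are translated
independently and never used for pair repair. Records in any order are
accepted, at the cost of holding unmatched primaries in memory until
their mate appears.

## What the synthetic data does and does not emulate

The generator (`splicelift.fixtures`) produces uniform-composition random
genomes, uniformly placed multi-exon transcripts (a configurable subset
with one sub-flank internal exon to force multi-exon spanning), and reads
sampled from spliced transcript sequence or raw genome with origin
recorded — so truth alignments are *recomputed* from the origin by an
exon-chain walk that never consults junction-record blocks, making it a
genuine oracle for the translation path. Default scale is two 50 kb
chromosomes, 30 transcripts and 2,000 reads of 100 bp: seconds on one
CPU, while still yielding on the order of 800 junction-crossing reads and
~100 junction sequences per scenario. Base qualities are constant and the
optional mutator introduces mismatches only (never indels), drawn from an
RNG stream separate from the structural one, so coordinates are identical
across mismatch rates. Expression levels, fragment-size distributions,
sequencing-error profiles and genome repeat structure are *not* modelled:
passing tests demonstrate coordinate and bookkeeping correctness, not
robustness to repeat-induced mismapping, which is the aligner's province.

The acceptance script runs 20 such scenarios (~16,000 junction
translations, ~1,400 of them multi-exon spanning), two exhaustively
checked references, an enumerated table of 31 pair/MAPQ edge cases, and a
1,500-read single-end round trip through BWA-MEM when the binary is
available; these sizes were chosen to exercise every code path within a
few seconds.

## Known limitations

- Only annotated junctions exist in the extension; novel junctions are
  invisible by construction.
- Reads longer than the build's `read_length` can overhang junction
  sequences and be dropped as boundary artifacts; the map records its
  read length and `translate --expect-read-length` guards against mixups.
- Soft-clipped tails are not re-examined for splice evidence.
- A genomic alignment whose mate never appears in the stream keeps its
  original mate fields, which may reference extended coordinates; pairs
  are only repaired when both primaries are seen.
- MAPQ restoration trusts the aligner's alternative-hit tag; aligners
  that suppress it for highly repetitive hits leave MAPQ 0 untouched.
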