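"""Synthetic genomes, annotations and reads with known truth alignments.

Everything the other modules need to be exercised end to end is generated
here from a seed: a random genome, multi-exon transcript models (including
transcripts with exons deliberately shorter than the flank, so junction
sequences cross several exons), and reads sampled from spliced transcript
sequence or raw genome with their origin recorded.  Because placement is
known by construction, reads can be emitted as already-aligned SAM records
against the extended reference — standing in for an external aligner — and
an exon-chain-walk oracle, deliberately independent of junction-record
blocks, gives the expected per-base genomic coordinates of every read.

The generator emulates coordinate structure, not sequencing realism:
constant base qualities, uniform base composition, optional
mismatch-only perturbation, no expression or fragment-size modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .annotation import ExonInterval, TranscriptModel
from .refbuild import ExtendedReference, build_junction_blocks
from .annotation import Junction
from .translate import (
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    AlignmentRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioParams",
    "SimRead",
    "SyntheticScenario",
    "TruthAlignment",
    "make_scenario",
    "reads_to_sam",
    "oracle_project",
    "write_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of the synthetic scenario generator.

    Defaults are desk-scale: two 50 kb chromosomes, 30 transcripts, 100 bp
    reads — seconds on one CPU.  ``n_short_exon_transcripts`` transcripts
    get one internal exon shorter than the flank, forcing multi-exon
    junction sequences and truth CIGARs with two or more N operators.
    """

    n_chroms: int = 2
    chrom_length: int = 50_000
    n_transcripts: int = 30
    n_short_exon_transcripts: int = 6
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (80, 300)
    short_exon_length_range: tuple[int, int] = (8, 40)
    intron_length_range: tuple[int, int] = (100, 1000)
    read_length: int = 100
    n_reads: int = 2000
    junction_read_fraction: float = 0.5
    paired_fraction: float = 0.5
    insert_range: tuple[int, int] = (150, 400)
    min_overhang: int = 1
    mismatch_rate: float = 0.0
    base_quality: int = 30

    def validate(self) -> "ScenarioParams":
        if self.exon_length_range[0] < 1 or self.intron_length_range[0] < 1:
            raise ValueError("exon and intron lengths must be >= 1")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        max_spliced = self.exon_count_range[1] * self.exon_length_range[1]
        if self.read_length > max_spliced:
            raise ValueError(
                f"read_length {self.read_length} exceeds the longest possible "
                f"spliced transcript ({max_spliced})"
            )
        if not 0 <= self.junction_read_fraction <= 1:
            raise ValueError("junction_read_fraction must be in [0, 1]")
        return self


@dataclass(frozen=True)
class SimRead:
    """One simulated read and where it came from.

    ``start`` is a genomic 0-based coordinate for genomic-origin reads and
    an offset into the forward-strand spliced sequence for transcript
    reads (transcript strand does not enter coordinate bookkeeping; a
    ``reverse`` read is emitted reverse-complemented).
    """

    name: str
    seq: str
    qual: str
    origin: str  # 'genomic' | 'transcript'
    chrom: str
    transcript_id: str | None
    start: int
    reverse: bool
    mate: int = 0  # 0 unpaired, 1 first-in-pair, 2 second-in-pair


@dataclass
class TruthAlignment:
    """Expected genomic alignment of a read, recomputed from its origin."""

    chrom: str
    pos: int  # 1-based
    cigar: str  # with N gaps for junction-crossing reads
    reverse: bool
    # Extended-reference placement; None when the read does not cross a junction.
    ext_rname: str | None = None
    ext_pos: int | None = None  # 1-based
    ext_cigar: str | None = None


@dataclass
class SyntheticScenario:
    params: ScenarioParams
    seed: int
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    reads: list[SimRead]
    _tx_by_id: dict[str, TranscriptModel] = field(default=None, repr=False)

    @property
    def read_length(self) -> int:
        return self.params.read_length

    def transcript(self, transcript_id: str) -> TranscriptModel:
        if self._tx_by_id is None:
            self._tx_by_id = {t.transcript_id: t for t in self.transcripts}
        return self._tx_by_id[transcript_id]

    def junction_reads(self) -> Iterator[SimRead]:
        """Reads whose truth alignment crosses at least one junction."""
        for read in self.reads:
            if read.origin == "transcript" and "N" in self.truth(read).cigar:
                yield read

    # -- truth --------------------------------------------------------
    def truth(self, read: SimRead) -> TruthAlignment:
        coords = oracle_project(read, self)
        cigar = _coords_to_cigar(coords)
        return TruthAlignment(
            chrom=read.chrom, pos=coords[0] + 1, cigar=cigar, reverse=read.reverse
        )


def _coords_to_cigar(coords: list[int]) -> str:
    """Turn strictly increasing per-base genomic coordinates into M/N runs."""
    ops: list[str] = []
    run = 1
    for prev, cur in zip(coords, coords[1:]):
        gap = cur - prev - 1
        if gap == 0:
            run += 1
        else:
            ops.append(f"{run}M{gap}N")
            run = 1
    ops.append(f"{run}M")
    return "".join(ops)


def oracle_project(read: SimRead, scenario: SyntheticScenario) -> list[int]:
    """Genomic 0-based coordinate of every read base, by exon-chain walk.

    For transcript reads this walks the exon chain base by base — an
    implementation deliberately independent of junction-record blocks — so
    it can serve as an oracle for the translation path.  Coordinates are
    reported in forward-strand read order.
    """
    if read.origin == "genomic":
        return list(range(read.start, read.start + len(read.seq)))
    tx = scenario.transcript(read.transcript_id)
    per_base: list[int] = []
    tpos = 0
    for exon in tx.exons:
        for g in range(exon.start, exon.end):
            if read.start <= tpos < read.start + len(read.seq):
                per_base.append(g)
            tpos += 1
    if len(per_base) != len(read.seq):
        raise ValueError(
            f"read {read.name} extends past transcript {tx.transcript_id}"
        )
    return per_base


# ---------------------------------------------------------------------------
# generation


def _random_genome(rng: np.random.Generator, params: ScenarioParams) -> dict[str, str]:
    return {
        f"chr{i + 1}": (
            rng.choice(_BASES, size=params.chrom_length).tobytes().decode()
        )
        for i in range(params.n_chroms)
    }


def _random_transcript(
    rng: np.random.Generator,
    params: ScenarioParams,
    chrom: str,
    chrom_len: int,
    tid: str,
    with_short_exon: bool,
) -> TranscriptModel | None:
    n_exons = int(rng.integers(*params.exon_count_range, endpoint=True))
    if with_short_exon:
        n_exons = max(n_exons, 3)
    exon_lens = [
        int(rng.integers(*params.exon_length_range, endpoint=True))
        for _ in range(n_exons)
    ]
    if with_short_exon:
        # A short internal exon below the flank length forces junction
        # sequences (and reads) to cross more than two exons.
        exon_lens[int(rng.integers(1, n_exons - 1))] = int(
            rng.integers(*params.short_exon_length_range, endpoint=True)
        )
    intron_lens = [
        int(rng.integers(*params.intron_length_range, endpoint=True))
        for _ in range(n_exons - 1)
    ]
    span = sum(exon_lens) + sum(intron_lens)
    if span >= chrom_len:
        return None
    start = int(rng.integers(0, chrom_len - span))
    exons: list[ExonInterval] = []
    cursor = start
    for i, elen in enumerate(exon_lens):
        exons.append(ExonInterval(chrom, cursor, cursor + elen))
        cursor += elen
        if i < n_exons - 1:
            cursor += intron_lens[i]
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(
        transcript_id=tid, gene_id=f"G_{tid}", chrom=chrom, strand=strand, exons=exons
    ).validate()


def _junction_tpos(tx: TranscriptModel) -> list[int]:
    """Spliced-coordinate positions of each donor boundary (forward order)."""
    out = []
    acc = 0
    for exon in tx.exons[:-1]:
        acc += exon.length
        out.append(acc)
    return out


def _sample_junction_read(
    rng: np.random.Generator,
    params: ScenarioParams,
    tx: TranscriptModel,
    spliced: str,
) -> int | None:
    """Pick a spliced-sequence start so the read crosses >= 1 junction."""
    L = params.read_length
    if tx.spliced_length < L or len(tx.exons) < 2:
        return None
    boundaries = _junction_tpos(tx)
    d = int(boundaries[rng.integers(0, len(boundaries))])
    # overhang of at least min_overhang on each side of the chosen boundary
    lo = max(0, d - L + params.min_overhang)
    hi = min(tx.spliced_length - L, d - params.min_overhang)
    if lo > hi:
        return None
    return int(rng.integers(lo, hi, endpoint=True))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def make_scenario(params: ScenarioParams | None = None, seed: int = 0) -> SyntheticScenario:
    """Generate a deterministic synthetic scenario from a seed."""
    params = (params or ScenarioParams()).validate()
    rng = np.random.default_rng(seed)
    # Separate stream for sequence errors: scenario structure (transcripts,
    # read placements, truth coordinates) is identical across mismatch rates.
    mut_rng = np.random.default_rng([seed, 1])
    genome = _random_genome(rng, params)
    chroms = list(genome)

    transcripts: list[TranscriptModel] = []
    attempts = 0
    while len(transcripts) < params.n_transcripts and attempts < params.n_transcripts * 20:
        attempts += 1
        tid = f"T{len(transcripts) + 1:04d}"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        tx = _random_transcript(
            rng, params, chrom, len(genome[chrom]), tid,
            with_short_exon=len(transcripts) < params.n_short_exon_transcripts,
        )
        if tx is not None:
            transcripts.append(tx)
    if len(transcripts) < params.n_transcripts:
        raise ValueError(
            "could not place the requested transcripts; chromosomes too short "
            "for the exon/intron length ranges"
        )

    spliced = {t.transcript_id: t.spliced_sequence(genome) for t in transcripts}
    eligible = [
        t for t in transcripts
        if len(t.exons) >= 2 and t.spliced_length >= params.read_length
    ]
    if not eligible:
        raise ValueError("no transcript long enough to yield junction reads")

    reads: list[SimRead] = []
    qual = chr(33 + params.base_quality) * params.read_length
    L = params.read_length
    serial = 0
    while len(reads) < params.n_reads:
        serial += 1
        paired = rng.random() < params.paired_fraction
        junctional = rng.random() < params.junction_read_fraction
        if junctional:
            tx = eligible[int(rng.integers(0, len(eligible)))]
            t_start = _sample_junction_read(rng, params, tx, spliced[tx.transcript_id])
            if t_start is None:
                continue
            origin, chrom, tid = "transcript", tx.chrom, tx.transcript_id
            source, source_len = spliced[tid], tx.spliced_length
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            origin, tid = "genomic", None
            source, source_len = genome[chrom], len(genome[chrom])
            t_start = int(rng.integers(0, source_len - L))

        name = f"read{serial:06d}"
        rev1 = bool(rng.random() < 0.5)
        seq1 = _mutate(mut_rng, source[t_start:t_start + L], params.mismatch_rate)
        if paired:
            insert = int(rng.integers(*params.insert_range, endpoint=True))
            m_start = t_start + insert - L
            if m_start < 0 or m_start + L > source_len or m_start < t_start:
                paired = False
        if not paired:
            reads.append(SimRead(name, seq1, qual, origin, chrom, tid, t_start, rev1))
            continue
        seq2 = _mutate(mut_rng, source[m_start:m_start + L], params.mismatch_rate)
        # FR pair: leftmost mate forward, rightmost reverse.
        reads.append(SimRead(name, seq1, qual, origin, chrom, tid, t_start, False, mate=1))
        reads.append(SimRead(name, seq2, qual, origin, chrom, tid, m_start, True, mate=2))

    log.info(
        "scenario seed=%d: %d transcripts, %d reads (%d junction-crossing)",
        seed, len(transcripts), len(reads),
        sum(1 for _ in SyntheticScenario(params, seed, genome, transcripts, reads).junction_reads()),
    )
    return SyntheticScenario(
        params=params, seed=seed, genome=genome, transcripts=transcripts, reads=reads
    )


# ---------------------------------------------------------------------------
# placement against the extended reference (the aligner stand-in)


def _crossed_junctions(
    read: SimRead, tx: TranscriptModel
) -> Iterator[tuple[Junction, int]]:
    """Junctions the read crosses with >= 1 base on each side.

    Yields (junction, donor position in spliced coordinates).
    """
    boundaries = _junction_tpos(tx)
    for i, d in enumerate(boundaries):
        if read.start < d < read.start + len(read.seq):
            left, right = tx.exons[i], tx.exons[i + 1]
            if left.end == right.start:
                continue
            yield (
                Junction(tx.chrom, left.end, right.start,
                         frozenset({tx.transcript_id})),
                d,
            )


def _extended_placement(
    read: SimRead, scenario: SyntheticScenario, ext_ref: ExtendedReference
) -> tuple[str, int] | None:
    """(rname, 1-based pos) of the read within a junction region, or None."""
    if read.origin != "transcript":
        return None
    tx = scenario.transcript(read.transcript_id)
    crossed = list(_crossed_junctions(read, tx))
    if not crossed:
        return None
    # Any crossed junction whose sequence window contains the whole read
    # can host it; with full flanks the first one always does.
    for junction, donor_tpos in crossed:
        blocks = tuple(build_junction_blocks(junction, tx, ext_ref.flank))
        jrec = ext_ref.record_for_blocks(tx.chrom, blocks)
        left_len = sum(b.length for b in blocks if b.end <= junction.donor_end)
        offset = read.start - donor_tpos + left_len
        if 0 <= offset and offset + len(read.seq) <= jrec.length:
            return jrec.chrom, jrec.ext_start + offset + 1
    raise ValueError(
        f"read {read.name} crosses a junction but fits no junction sequence; "
        "scenario bookkeeping is inconsistent"
    )


def reads_to_sam(
    scenario: SyntheticScenario, ext_ref: ExtendedReference
) -> list[AlignmentRecord]:
    """Emit each read as an ungapped SAM record against the extended reference.

    Placement is known by construction — no alignment search happens.
    Junction-crossing reads are placed inside their junction region;
    everything else is placed genomically.  Paired reads get consistent
    mate fields in extended coordinates.
    """
    records: list[AlignmentRecord] = []
    placements: dict[tuple[str, int], tuple[str, int]] = {}
    L = scenario.read_length
    for read in scenario.reads:
        placed = _extended_placement(read, scenario, ext_ref)
        if placed is None:
            # Genomic placement: a non-junction-crossing transcript read lies
            # within one exon, so its first oracle coordinate starts a
            # contiguous genomic alignment.
            if read.origin == "genomic":
                placed = (read.chrom, read.start + 1)
            else:
                placed = (read.chrom, oracle_project(read, scenario)[0] + 1)
        placements[(read.name, read.mate)] = placed
    for read in scenario.reads:
        rname, pos = placements[(read.name, read.mate)]
        flag = FLAG_REVERSE if read.reverse else 0
        rnext, pnext, tlen = "*", 0, 0
        if read.mate:
            flag |= FLAG_PAIRED | (FLAG_READ1 if read.mate == 1 else FLAG_READ2)
            mate_rname, mate_pos = placements[(read.name, 3 - read.mate)]
            mate_rev = not read.reverse  # pairs are generated FR
            if mate_rev:
                flag |= FLAG_MATE_REVERSE
            rnext = "=" if mate_rname == rname else mate_rname
            pnext = mate_pos
            if mate_rname == rname:
                span = max(pos, mate_pos) + L - min(pos, mate_pos)
                tlen = span if pos <= mate_pos else -span
                flag |= FLAG_PROPER
        # SAM stores SEQ in reference-forward orientation, so a
        # reverse-strand record carries the forward-strand substring; the
        # reverse complement only appears in FASTQ output.
        records.append(
            AlignmentRecord(
                qname=read.name, flag=flag, rname=rname, pos=pos, mapq=60,
                cigar=[(len(read.seq), "M")], rnext=rnext, pnext=pnext,
                tlen=tlen, seq=read.seq, qual=read.qual,
            )
        )
    return records


# ---------------------------------------------------------------------------
# file writers (so the same fixtures can drive a real external aligner)


def write_scenario_fasta(scenario: SyntheticScenario, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in scenario.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_scenario_gtf(scenario: SyntheticScenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in scenario.transcripts:
            for n, exon in enumerate(tx.exons, start=1):
                start1, end1 = exon.to_gtf_coords()
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'exon_number "{n}";'
                )
                fh.write(
                    f"{tx.chrom}\tsplicelift\texon\t{start1}\t{end1}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


def write_scenario_fastq(scenario: SyntheticScenario, path1: str | Path,
                         path2: str | Path | None = None) -> None:
    """Write reads as FASTQ; paired reads split across two files when given."""
    fh1 = open(path1, "w")
    fh2 = open(path2, "w") if path2 is not None else None
    try:
        for read in scenario.reads:
            seq = revcomp(read.seq) if read.reverse else read.seq
            entry = f"@{read.name}\n{seq}\n+\n{read.qual}\n"
            if read.mate == 2 and fh2 is not None:
                fh2.write(entry)
            elif read.mate == 0 or read.mate == 1 or fh2 is None:
                fh1.write(entry)
    finally:
        fh1.close()
        if fh2 is not None:
            fh2.close()


def write_scenario_sam(
    scenario: SyntheticScenario, ext_ref: ExtendedReference, path: str | Path
) -> None:
    """Write the aligner-stand-in records as a SAM file with a matching header."""
    jmap = ext_ref.junction_map
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in ext_ref.sequences:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{jmap.extended_length(chrom)}\n")
        for rec in reads_to_sam(scenario, ext_ref):
            fh.write(rec.to_sam_line() + "\n")


def write_scenario(
    scenario: SyntheticScenario, out_dir: str | Path,
    ext_ref: ExtendedReference | None = None,
) -> dict[str, Path]:
    """Write genome, annotation, reads (and optionally SAM) into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "gtf": out_dir / "transcripts.gtf",
        "reads1": out_dir / "reads_1.fastq",
        "reads2": out_dir / "reads_2.fastq",
    }
    write_scenario_fasta(scenario, paths["genome"])
    write_scenario_gtf(scenario, paths["gtf"])
    write_scenario_fastq(scenario, paths["reads1"], paths["reads2"])
    if ext_ref is not None:
        paths["sam"] = out_dir / "aligned_extended.sam"
        write_scenario_sam(scenario, ext_ref, paths["sam"])
    return paths
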