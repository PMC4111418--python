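"""Junction-extended reference construction.

The alignment target is the genome with one junction-spanning sequence per
distinct junction neighbourhood appended after each chromosome's genomic
sequence.  A junction-spanning sequence carries up to ``flank`` exonic
bases on each side of the splice boundary, where the flank is sized from
the read length so that no full-length read can sit entirely on one side:
with ``flank = read_length - min_overhang`` (default overhang 1), every
read-length window of a fully-flanked junction sequence crosses the
boundary, keeping unspliced reads out of the junction portion.

When the adjacent exon is shorter than the flank, the walk continues into
the next exon of the same transcript, so a junction sequence may be built
from more than two genomic blocks and a single read may span several
exons.  The ordered block list is exactly the information needed to
project alignments back onto the genome, and is persisted alongside the
FASTA as a plain-text junction map.

The extension must be rebuilt once per read length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import (
    AnnotationValidationError,
    ExonInterval,
    Junction,
    TranscriptModel,
    enumerate_junctions,
)

log = logging.getLogger(__name__)

__all__ = [
    "JunctionRecord",
    "JunctionMap",
    "ExtendedReference",
    "ReferenceBuildError",
    "JunctionMapFormatError",
    "flank_length",
    "build_junction_blocks",
    "build_extended_reference",
    "write_junction_map",
    "read_junction_map",
    "write_extended_fasta",
    "read_fasta",
]

_MAP_MAGIC = "#splicelift-jmap\tv1"


class ReferenceBuildError(ValueError):
    pass


class JunctionMapFormatError(ValueError):
    pass


def flank_length(read_length: int, min_overhang: int = 1) -> int:
    """Exonic bases to take on each side of a junction.

    ``read_length - min_overhang``: no read of ``read_length`` bases fits
    within one full flank, so every full-length alignment to a fully
    flanked junction sequence must cross the splice boundary by at least
    ``min_overhang`` bases.
    """
    if read_length < 2:
        raise ReferenceBuildError(f"read_length must be >= 2, got {read_length}")
    if not 1 <= min_overhang < read_length:
        raise ReferenceBuildError(
            f"min_overhang must satisfy 1 <= min_overhang < read_length, "
            f"got {min_overhang} with read_length {read_length}"
        )
    return read_length - min_overhang


@dataclass(frozen=True)
class JunctionRecord:
    """Placement of one junction-spanning sequence in the extended reference.

    ``blocks`` are the ordered genomic intervals whose concatenation (on
    the forward strand) is the junction sequence occupying
    ``[ext_start, ext_start + length)`` of the extended chromosome.
    """

    junction_id: str
    chrom: str
    ext_start: int
    length: int
    blocks: tuple[ExonInterval, ...]
    transcript_ids: tuple[str, ...]

    def validate(self, original_length: int | None = None) -> "JunctionRecord":
        if len(self.blocks) < 2:
            raise ReferenceBuildError(
                f"junction {self.junction_id}: needs >= 2 blocks, got {len(self.blocks)}"
            )
        if self.length != sum(b.length for b in self.blocks):
            raise ReferenceBuildError(
                f"junction {self.junction_id}: length {self.length} != sum of blocks"
            )
        for left, right in zip(self.blocks, self.blocks[1:]):
            if right.start <= left.end:
                raise ReferenceBuildError(
                    f"junction {self.junction_id}: blocks not strictly ascending"
                )
        if original_length is not None and self.ext_start < original_length:
            raise ReferenceBuildError(
                f"junction {self.junction_id}: ext_start {self.ext_start} lies "
                f"within the genomic sequence (length {original_length})"
            )
        return self

    @property
    def ext_end(self) -> int:
        return self.ext_start + self.length


@dataclass
class JunctionMap:
    """Junction records plus the build parameters needed to translate with them."""

    read_length: int
    flank: int
    spacer: int
    original_lengths: dict[str, int]
    records: list[JunctionRecord]
    _by_chrom: dict[str, list[JunctionRecord]] = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> "JunctionMap":
        for rec in self.records:
            if rec.chrom not in self.original_lengths:
                raise ReferenceBuildError(
                    f"junction {rec.junction_id}: unknown chromosome {rec.chrom}"
                )
            rec.validate(self.original_lengths[rec.chrom])
        return self

    def records_for(self, chrom: str) -> list[JunctionRecord]:
        if self._by_chrom is None:
            by: dict[str, list[JunctionRecord]] = {}
            for rec in self.records:
                by.setdefault(rec.chrom, []).append(rec)
            for recs in by.values():
                recs.sort(key=lambda r: r.ext_start)
            object.__setattr__(self, "_by_chrom", by)
        return self._by_chrom.get(chrom, [])

    def extended_length(self, chrom: str) -> int:
        return self.original_lengths[chrom] + sum(
            self.spacer + r.length for r in self.records_for(chrom)
        )


@dataclass
class ExtendedReference:
    """Genome sequences with junction regions appended, plus their map."""

    sequences: dict[str, str]
    junction_map: JunctionMap
    _by_blocks: dict[tuple[str, tuple[ExonInterval, ...]], JunctionRecord] = field(
        default=None, repr=False, compare=False
    )

    @property
    def records(self) -> list[JunctionRecord]:
        return self.junction_map.records

    @property
    def original_lengths(self) -> dict[str, int]:
        return self.junction_map.original_lengths

    @property
    def read_length(self) -> int:
        return self.junction_map.read_length

    @property
    def flank(self) -> int:
        return self.junction_map.flank

    @property
    def spacer(self) -> int:
        return self.junction_map.spacer

    def record_for_blocks(
        self, chrom: str, blocks: Sequence[ExonInterval]
    ) -> JunctionRecord:
        """Look up the placed record whose block tuple matches exactly."""
        if self._by_blocks is None:
            self._by_blocks = {
                (r.chrom, r.blocks): r for r in self.junction_map.records
            }
        return self._by_blocks[(chrom, tuple(blocks))]


def build_junction_blocks(
    junction: Junction, transcript: TranscriptModel, flank: int
) -> list[ExonInterval]:
    """Genomic blocks of the junction-spanning sequence for one transcript.

    Accumulates up to ``flank`` bases leftward from the donor end walking
    backward through the transcript's exon chain, and up to ``flank``
    bases rightward from the acceptor start walking forward, crossing into
    neighbouring exons whenever the adjacent exon is shorter than the
    remaining flank.  Flanks are truncated at the transcript termini, so
    the total may be shorter than ``2 * flank``.  Returns the merged block
    list in ascending genomic order.
    """
    exon_index = None
    for i, (left, right) in enumerate(zip(transcript.exons, transcript.exons[1:])):
        if left.end == junction.donor_end and right.start == junction.acceptor_start:
            exon_index = i
            break
    if exon_index is None:
        raise ReferenceBuildError(
            f"junction {junction.chrom}:{junction.donor_end}-{junction.acceptor_start} "
            f"is not an adjacent exon pair of transcript {transcript.transcript_id}"
        )

    left_blocks: list[ExonInterval] = []
    remaining = flank
    for exon in reversed(transcript.exons[: exon_index + 1]):
        if remaining <= 0:
            break
        take = min(remaining, exon.length)
        left_blocks.append(ExonInterval(exon.chrom, exon.end - take, exon.end))
        remaining -= take
    left_blocks.reverse()

    right_blocks: list[ExonInterval] = []
    remaining = flank
    for exon in transcript.exons[exon_index + 1:]:
        if remaining <= 0:
            break
        take = min(remaining, exon.length)
        right_blocks.append(ExonInterval(exon.chrom, exon.start, exon.start + take))
        remaining -= take

    blocks = left_blocks + right_blocks
    # Abutting exons elsewhere in the chain would yield touching blocks;
    # merge them so every inter-block gap is a real intron.
    merged: list[ExonInterval] = []
    for block in blocks:
        if merged and merged[-1].end == block.start:
            merged[-1] = ExonInterval(block.chrom, merged[-1].start, block.end)
        else:
            merged.append(block)
    return merged


def build_extended_reference(
    genome: Mapping[str, str],
    models: Iterable[TranscriptModel],
    read_length: int,
    min_overhang: int = 1,
    spacer: int | None = None,
) -> ExtendedReference:
    """Build the junction-extended reference for one read length.

    For every junction of every transcript the block list is computed; block
    lists identical in (chrom, block tuple) are emitted once (transcript ids
    unioned), while the same splice boundary seen through different
    short-exon neighbourhoods yields separate junction sequences because
    they project differently.  Each junction sequence is preceded by
    ``spacer`` ``'N'`` padding characters (default: one read length) so
    alignments cannot bridge unrelated regions, and appended after the
    chromosome's genomic sequence in deterministic order.
    """
    models = list(models)
    flank = flank_length(read_length, min_overhang)
    if spacer is None:
        spacer = read_length
    if spacer < 0:
        raise ReferenceBuildError(f"spacer must be >= 0, got {spacer}")

    by_id = {m.transcript_id: m for m in models}
    for model in models:
        if model.chrom not in genome:
            raise ReferenceBuildError(
                f"transcript {model.transcript_id}: chromosome {model.chrom} "
                "absent from genome"
            )
        chrom_len = len(genome[model.chrom])
        for exon in model.exons:
            if exon.end > chrom_len:
                raise ReferenceBuildError(
                    f"transcript {model.transcript_id}: exon "
                    f"{exon.start}-{exon.end} exceeds {model.chrom} length {chrom_len}"
                )
    junctions = enumerate_junctions(models)

    # (chrom, blocks) -> [sort key, transcript id set]
    placed: dict[tuple[str, tuple[ExonInterval, ...]], list] = {}
    for junction in junctions:
        if junction.chrom not in genome:
            raise ReferenceBuildError(
                f"junction chromosome {junction.chrom} absent from genome"
            )
        chrom_len = len(genome[junction.chrom])
        if junction.acceptor_start >= chrom_len or junction.donor_end > chrom_len:
            raise ReferenceBuildError(
                f"junction {junction.chrom}:{junction.donor_end}-"
                f"{junction.acceptor_start} exceeds chromosome length {chrom_len}"
            )
        for tid in sorted(junction.transcript_ids):
            blocks = tuple(build_junction_blocks(junction, by_id[tid], flank))
            if blocks[-1].end > chrom_len:
                raise ReferenceBuildError(
                    f"junction {junction.chrom}:{junction.donor_end}-"
                    f"{junction.acceptor_start}: block exceeds chromosome length"
                )
            key = (junction.chrom, blocks)
            sort_key = (
                junction.chrom,
                junction.donor_end,
                junction.acceptor_start,
                tuple((b.start, b.end) for b in blocks),
            )
            if key in placed:
                placed[key][1].add(tid)
                placed[key][0] = min(placed[key][0], sort_key)
            else:
                placed[key] = [sort_key, {tid}]

    ordered = sorted(placed.items(), key=lambda kv: kv[1][0])
    n_candidates = sum(len(j.transcript_ids) for j in junctions)
    log.info(
        "placing %d junction sequences (%d junctions, %d candidate block lists, "
        "%d deduplicated)",
        len(ordered), len(junctions), n_candidates, n_candidates - len(ordered),
    )

    original_lengths = {chrom: len(seq) for chrom, seq in genome.items()}
    cursors = dict(original_lengths)
    parts: dict[str, list[str]] = {chrom: [genome[chrom]] for chrom in genome}
    records: list[JunctionRecord] = []
    id_counts: dict[tuple[str, int, int], int] = {}
    for (chrom, blocks), (sort_key, tids) in ordered:
        donor_end, acceptor_start = sort_key[1], sort_key[2]
        n_seen = id_counts.get((chrom, donor_end, acceptor_start), 0)
        id_counts[(chrom, donor_end, acceptor_start)] = n_seen + 1
        junction_id = f"{chrom}:{donor_end}-{acceptor_start}"
        if n_seen:
            junction_id += f".{n_seen + 1}"
        seq = "".join(genome[chrom][b.start:b.end] for b in blocks)
        ext_start = cursors[chrom] + spacer
        parts[chrom].append("N" * spacer)
        parts[chrom].append(seq)
        cursors[chrom] = ext_start + len(seq)
        records.append(
            JunctionRecord(
                junction_id=junction_id,
                chrom=chrom,
                ext_start=ext_start,
                length=len(seq),
                blocks=blocks,
                transcript_ids=tuple(sorted(tids)),
            )
        )

    jmap = JunctionMap(
        read_length=read_length,
        flank=flank,
        spacer=spacer,
        original_lengths=original_lengths,
        records=records,
    ).validate()
    sequences = {chrom: "".join(chunks) for chrom, chunks in parts.items()}
    return ExtendedReference(sequences=sequences, junction_map=jmap)


# ---------------------------------------------------------------------------
# persistence


def write_junction_map(ref: ExtendedReference | JunctionMap, path: str | Path) -> None:
    """Write the junction map as tab-delimited text with a '#' header block."""
    jmap = ref.junction_map if isinstance(ref, ExtendedReference) else ref
    jmap.validate()
    with open(path, "w") as fh:
        fh.write(_MAP_MAGIC + "\n")
        fh.write(f"#read_length\t{jmap.read_length}\n")
        fh.write(f"#flank\t{jmap.flank}\n")
        fh.write(f"#spacer\t{jmap.spacer}\n")
        for chrom, length in jmap.original_lengths.items():
            fh.write(f"#chrom\t{chrom}\t{length}\n")
        fh.write(
            "#junction_id\tchrom\text_start\tlength\tblocks\ttranscript_ids\n"
        )
        for rec in jmap.records:
            blocks = ",".join(f"{b.start}-{b.end}" for b in rec.blocks)
            tids = ";".join(rec.transcript_ids)
            fh.write(
                f"{rec.junction_id}\t{rec.chrom}\t{rec.ext_start}\t{rec.length}"
                f"\t{blocks}\t{tids}\n"
            )


def read_junction_map(path: str | Path) -> JunctionMap:
    """Load a junction map, validating version, header and record invariants."""
    path = Path(path)
    read_length = flank = spacer = None
    original_lengths: dict[str, int] = {}
    records: list[JunctionRecord] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAP_MAGIC:
            raise JunctionMapFormatError(
                f"{path}: not a junction map (bad magic line {first!r})"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if fields[0] == "read_length":
                    read_length = int(fields[1])
                elif fields[0] == "flank":
                    flank = int(fields[1])
                elif fields[0] == "spacer":
                    spacer = int(fields[1])
                elif fields[0] == "chrom":
                    original_lengths[fields[1]] = int(fields[2])
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise JunctionMapFormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            jid, chrom, ext_start, length, blocks_s, tids_s = fields
            try:
                blocks = tuple(
                    ExonInterval(chrom, int(b.split("-")[0]), int(b.split("-")[1]))
                    for b in blocks_s.split(",")
                )
            except (ValueError, IndexError, AnnotationValidationError) as exc:
                raise JunctionMapFormatError(f"{path}:{lineno}: bad blocks field") from exc
            records.append(
                JunctionRecord(
                    junction_id=jid,
                    chrom=chrom,
                    ext_start=int(ext_start),
                    length=int(length),
                    blocks=blocks,
                    transcript_ids=tuple(t for t in tids_s.split(";") if t),
                )
            )
    if read_length is None or flank is None or spacer is None:
        raise JunctionMapFormatError(
            f"{path}: truncated or incomplete header (read_length/flank/spacer)"
        )
    jmap = JunctionMap(
        read_length=read_length,
        flank=flank,
        spacer=spacer,
        original_lengths=original_lengths,
        records=records,
    )
    try:
        jmap.validate()
    except ReferenceBuildError as exc:
        raise JunctionMapFormatError(f"{path}: {exc}") from exc
    return jmap


def write_extended_fasta(
    ref: ExtendedReference, path: str | Path, line_width: int = 60
) -> None:
    """Write the extended reference as FASTA, one record per chromosome."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for chrom, seq in ref.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }
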