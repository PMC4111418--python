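"""Translation of extended-reference alignments into genomic alignments.

Reads aligned to a junction-spanning sequence carry ungapped CIGARs in
extended-reference coordinates.  This module projects them back onto the
genome: match/deletion runs are split wherever they cross a block
boundary and an ``N`` operator of exactly the intron length is inserted
between the pieces, positions are rewritten through the block list, mate
fields and the proper-pair flag are recomputed from the translated
coordinates, and mapping qualities zeroed by the genome/junction sequence
duplication are restored when every alternative hit collapses onto the
primary locus.

Alignments wholly inside the genomic portion of a chromosome pass through
untouched; alignments touching spacer padding or straddling region
boundaries are aligner artifacts and are set unmapped with a diagnostic
tag rather than aborting the run.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .refbuild import JunctionMap, JunctionRecord

log = logging.getLogger(__name__)

__all__ = [
    "Cigar",
    "AlignmentRecord",
    "AltHit",
    "TranslationOutcome",
    "TranslationSummary",
    "TranslationError",
    "parse_cigar",
    "cigar_to_str",
    "query_length",
    "reference_length",
    "merge_cigar",
    "classify_alignment",
    "project_offset",
    "translate_record",
    "repair_pair",
    "decode_alt_hits",
    "repair_mapq",
    "translate_stream",
]

# CIGAR op classes (SAM spec): which side each operator consumes.
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

Cigar = list  # list[tuple[int, str]]

SPACER_TAG = "XJ"  # diagnostic tag on records dropped as boundary artifacts

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class TranslationError(ValueError):
    pass


def parse_cigar(cigar: str) -> Cigar:
    if cigar == "*" or not cigar:
        return []
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if sum(len(f"{n}{op}") for n, op in ops) != len(cigar):
        raise TranslationError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_to_str(ops: Sequence[tuple[int, str]]) -> str:
    if not ops:
        return "*"
    return "".join(f"{n}{op}" for n, op in ops)


def query_length(ops: Sequence[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in QUERY_OPS)


def reference_length(ops: Sequence[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in REF_OPS)


def merge_cigar(ops: Iterable[tuple[int, str]]) -> Cigar:
    """Merge adjacent same-operator runs and drop zero-length entries."""
    merged: Cigar = []
    for n, op in ops:
        if n == 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return merged


@dataclass
class AlignmentRecord:
    """The semantic content of one SAM line.

    ``pos``/``pnext`` are 1-based as in SAM text (0 when unavailable);
    ``tags`` keeps the optional fields as raw ``TAG:TYPE:VALUE`` strings so
    pass-through records survive byte-identically.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: Cigar
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[str] = field(default_factory=list)

    @classmethod
    def from_sam_line(cls, line: str) -> "AlignmentRecord":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise TranslationError(
                f"SAM line has {len(fields)} fields, expected >= 11"
            )
        return cls(
            qname=fields[0],
            flag=int(fields[1]),
            rname=fields[2],
            pos=int(fields[3]),
            mapq=int(fields[4]),
            cigar=parse_cigar(fields[5]),
            rnext=fields[6],
            pnext=int(fields[7]),
            tlen=int(fields[8]),
            seq=fields[9],
            qual=fields[10],
            tags=fields[11:],
        )

    def to_sam_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            cigar_to_str(self.cigar),
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
            *self.tags,
        ]
        return "\t".join(fields)

    # -- flag helpers -------------------------------------------------
    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_primary(self) -> bool:
        return not self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)

    @property
    def reference_start(self) -> int:
        """0-based leftmost reference coordinate."""
        return self.pos - 1

    @property
    def reference_end(self) -> int:
        """0-based exclusive rightmost reference coordinate."""
        return self.pos - 1 + reference_length(self.cigar)

    def get_tag(self, tag: str) -> str | None:
        for t in self.tags:
            if t.startswith(tag + ":"):
                return t.split(":", 2)[2]
        return None

    def set_tag(self, tag: str, typ: str, value: str) -> None:
        self.drop_tag(tag)
        self.tags.append(f"{tag}:{typ}:{value}")

    def drop_tag(self, tag: str) -> None:
        self.tags = [t for t in self.tags if not t.startswith(tag + ":")]

    def copy(self) -> "AlignmentRecord":
        return replace(self, cigar=list(self.cigar), tags=list(self.tags))


@dataclass(frozen=True)
class AltHit:
    """One decoded alternative hit (BWA ``XA``-style): locus plus CIGAR."""

    rname: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    cigar_str: str
    nm: int = 0

    def encode(self) -> str:
        return f"{self.rname},{self.strand}{self.pos},{self.cigar_str},{self.nm}"


@dataclass
class TranslationOutcome:
    record: AlignmentRecord
    category: str  # genomic_passthrough | junction_translated | dropped_unmappable | unmapped_passthrough
    n_gaps_introduced: int = 0


@dataclass
class TranslationSummary:
    """Per-category record counts and the histogram of introduced N gaps."""

    counts: dict[str, int] = field(default_factory=dict)
    n_gaps_hist: dict[int, int] = field(default_factory=dict)

    def add(self, outcome: TranslationOutcome) -> None:
        self.counts[outcome.category] = self.counts.get(outcome.category, 0) + 1
        if outcome.category == "junction_translated":
            k = outcome.n_gaps_introduced
            self.n_gaps_hist[k] = self.n_gaps_hist.get(k, 0) + 1

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for cat in sorted(self.counts):
                fh.write(f"count.{cat}\t{self.counts[cat]}\n")
            for k in sorted(self.n_gaps_hist):
                fh.write(f"n_gaps.{k}\t{self.n_gaps_hist[k]}\n")


# ---------------------------------------------------------------------------
# classification and projection


def classify_alignment(
    rec: AlignmentRecord, jmap: JunctionMap
) -> tuple[str, JunctionRecord | None]:
    """Assign a record to {genomic, junction, spacer, unmapped}.

    ``genomic``: reference span entirely within the original chromosome.
    ``junction``: span entirely within one junction sequence (the matching
    :class:`JunctionRecord` is returned).  ``spacer``: anything touching
    padding or straddling a region boundary.
    """
    if rec.is_unmapped:
        return "unmapped", None
    if rec.rname not in jmap.original_lengths:
        raise TranslationError(
            f"record {rec.qname}: reference {rec.rname!r} absent from junction map"
        )
    start = rec.reference_start
    end = max(rec.reference_end, start + 1)
    if end <= jmap.original_lengths[rec.rname]:
        return "genomic", None
    for jrec in jmap.records_for(rec.rname):
        if jrec.ext_start <= start and end <= jrec.ext_end:
            return "junction", jrec
    return "spacer", None


def project_offset(offset: int, jrec: JunctionRecord) -> tuple[int, int]:
    """Project an offset within a junction sequence to (genomic pos, block index)."""
    if not 0 <= offset < jrec.length:
        raise TranslationError(
            f"offset {offset} outside junction {jrec.junction_id} "
            f"of length {jrec.length}"
        )
    consumed = 0
    for i, block in enumerate(jrec.blocks):
        if offset < consumed + block.length:
            return block.start + (offset - consumed), i
        consumed += block.length
    raise AssertionError("unreachable: offset within length but past all blocks")


def translate_record(rec: AlignmentRecord, jrec: JunctionRecord) -> AlignmentRecord:
    """Rewrite one junction-region alignment into genomic coordinates.

    Reference-consuming runs (M/D/=/X) are split at every block boundary
    they cross, with an ``N`` of the intervening intron length inserted
    between the pieces.  Query-only operators (I/S/H) attach to the
    preceding block's output (leading ones stay leading).  The sequence,
    qualities and strand are untouched; only POS and CIGAR change.
    """
    if rec.is_unmapped:
        raise TranslationError(f"record {rec.qname} is unmapped")
    offset = rec.reference_start - jrec.ext_start
    ref_len = reference_length(rec.cigar)
    if offset < 0 or offset + ref_len > jrec.length:
        raise TranslationError(
            f"record {rec.qname}: alignment [{offset}, {offset + ref_len}) not "
            f"contained in junction {jrec.junction_id} of length {jrec.length}"
        )

    # Block boundaries as cumulative offsets within the junction sequence.
    bounds: list[int] = []
    acc = 0
    for block in jrec.blocks:
        acc += block.length
        bounds.append(acc)

    def block_of(off: int) -> int:
        for i, b in enumerate(bounds):
            if off < b:
                return i
        return len(bounds) - 1

    out: list[tuple[int, str]] = []
    cursor = offset
    prev_block: int | None = None
    n_gaps = 0
    for n, op in rec.cigar:
        if op in ("I", "S", "H", "P"):
            out.append((n, op))
            continue
        if op not in REF_OPS:
            raise TranslationError(f"unsupported CIGAR operator {op!r}")
        remaining = n
        while remaining > 0:
            i = block_of(cursor)
            if prev_block is not None and i > prev_block:
                # Crossed into a new block — whether inside this op or
                # between two ref-consuming ops — so emit the intron gap.
                gap = jrec.blocks[i].start - jrec.blocks[prev_block].end
                out.append((gap, "N"))
                n_gaps += 1
            take = min(remaining, bounds[i] - cursor)
            out.append((take, op))
            cursor += take
            remaining -= take
            prev_block = i

    merged = merge_cigar(out)
    new_pos, _ = project_offset(offset, jrec)
    translated = rec.copy()
    translated.pos = new_pos + 1
    translated.cigar = merged
    return translated


# ---------------------------------------------------------------------------
# pair and MAPQ repair


def repair_pair(
    r1: AlignmentRecord, r2: AlignmentRecord, max_span: int = 1_000_000
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Recompute mate fields and the proper-pair flag from translated coordinates.

    The aligner judged pairing against the extended reference, where a
    junction-region mate sits megabases past the chromosome end; after
    translation the genomic span is what matters.  Proper pairing requires
    both mates mapped, on one chromosome, in FR orientation (forward mate
    leftmost), with genomic span (rightmost end - leftmost start) at most
    ``max_span``; TLEN is that span, signed positive on the leftmost mate.
    """
    if r1.qname != r2.qname:
        raise TranslationError(
            f"cannot pair records with different names: {r1.qname!r} vs {r2.qname!r}"
        )
    a, b = r1.copy(), r2.copy()
    for rec, mate in ((a, b), (b, a)):
        rec.flag &= ~(FLAG_PROPER | FLAG_MATE_UNMAPPED | FLAG_MATE_REVERSE)
        if mate.is_unmapped:
            rec.flag |= FLAG_MATE_UNMAPPED
            rec.rnext = "*" if rec.is_unmapped else "="
            rec.pnext = 0 if rec.is_unmapped else rec.pos
            rec.tlen = 0
            continue
        if mate.is_reverse:
            rec.flag |= FLAG_MATE_REVERSE
        rec.rnext = "=" if mate.rname == rec.rname else mate.rname
        rec.pnext = mate.pos

    if a.is_unmapped or b.is_unmapped or a.rname != b.rname:
        a.tlen = b.tlen = 0
        return a, b

    left, right = (a, b) if a.reference_start <= b.reference_start else (b, a)
    span = max(a.reference_end, b.reference_end) - min(
        a.reference_start, b.reference_start
    )
    left.tlen, right.tlen = span, -span
    fr = (not left.is_reverse) and right.is_reverse
    if fr and span <= max_span:
        a.flag |= FLAG_PROPER
        b.flag |= FLAG_PROPER
    return a, b


def decode_alt_hits(rec: AlignmentRecord, tag: str = "XA") -> list[AltHit] | None:
    """Decode the aligner's alternative-hit tag; None if absent or undecodable."""
    raw = rec.get_tag(tag)
    if raw is None:
        return None
    hits: list[AltHit] = []
    try:
        for part in raw.rstrip(";").split(";"):
            if not part:
                continue
            rname, strand_pos, cigar_str, nm = part.split(",")
            hits.append(
                AltHit(
                    rname=rname,
                    pos=int(strand_pos[1:]),
                    strand=strand_pos[0],
                    cigar_str=cigar_str,
                    nm=int(nm),
                )
            )
            if strand_pos[0] not in "+-":
                raise ValueError(f"bad strand in {part!r}")
    except (ValueError, IndexError):
        log.warning(
            "record %s: undecodable alternative-hit tag %r; passed through",
            rec.qname, raw,
        )
        return None
    return hits


def _translate_alt_hit(hit: AltHit, jmap: JunctionMap) -> AltHit | None:
    """Translate one alternative hit; None when it is a boundary artifact."""
    probe = AlignmentRecord(
        qname="", flag=0 if hit.strand == "+" else FLAG_REVERSE,
        rname=hit.rname, pos=hit.pos, mapq=0,
        cigar=parse_cigar(hit.cigar_str), rnext="*", pnext=0, tlen=0,
        seq="*", qual="*",
    )
    category, jrec = classify_alignment(probe, jmap)
    if category == "genomic":
        return hit
    if category == "junction":
        translated = translate_record(probe, jrec)
        return AltHit(
            rname=translated.rname,
            pos=translated.pos,
            strand=hit.strand,
            cigar_str=cigar_to_str(translated.cigar),
            nm=hit.nm,
        )
    return None


def repair_mapq(
    rec: AlignmentRecord,
    alt_hits: list[AltHit] | None,
    jmap: JunctionMap,
    restored_mapq: int = 60,
    tag: str = "XA",
) -> AlignmentRecord:
    """Restore mapping quality zeroed by genome/junction sequence duplication.

    Every alternative hit is translated to genomic coordinates; hits whose
    translated (rname, pos, strand, cigar) equal the primary's are the same
    locus seen through the junction copy of the sequence and are discarded.
    If the record had MAPQ 0 and every alternative collapses this way, the
    hit was unique after all: MAPQ becomes ``restored_mapq`` and the tag is
    removed.  Otherwise surviving alternatives are re-expressed in genomic
    coordinates and MAPQ is kept.
    """
    out = rec.copy()
    if alt_hits is None:
        return out
    primary_key = (
        out.rname,
        out.pos,
        "-" if out.is_reverse else "+",
        cigar_to_str(out.cigar),
    )
    survivors: list[AltHit] = []
    for hit in alt_hits:
        translated = _translate_alt_hit(hit, jmap)
        if translated is None:
            continue  # boundary artifact: not a real alternative locus
        key = (translated.rname, translated.pos, translated.strand, translated.cigar_str)
        if key == primary_key:
            continue
        survivors.append(translated)
    if not survivors:
        out.drop_tag(tag)
        if out.mapq == 0:
            out.mapq = restored_mapq
    else:
        out.set_tag(tag, "Z", ";".join(h.encode() for h in survivors) + ";")
    return out


# ---------------------------------------------------------------------------
# streaming


def _check_header(header: pysam.AlignmentHeader, jmap: JunctionMap) -> None:
    sq = {r["SN"]: r["LN"] for r in header.to_dict().get("SQ", [])}
    for chrom, orig_len in jmap.original_lengths.items():
        expected = jmap.extended_length(chrom)
        if chrom not in sq:
            raise TranslationError(
                f"header lacks @SQ for chromosome {chrom} recorded in the map"
            )
        if sq[chrom] != expected:
            raise TranslationError(
                f"header LN for {chrom} is {sq[chrom]}, but the junction map "
                f"implies an extended length of {expected} (original {orig_len}); "
                "this alignment run used a different reference than this map"
            )


def _genomic_header(
    header: pysam.AlignmentHeader, jmap: JunctionMap, pg_args: str | None
) -> pysam.AlignmentHeader:
    d = header.to_dict()
    d["SQ"] = [
        {**r, "LN": jmap.original_lengths[r["SN"]]}
        for r in d.get("SQ", [])
        if r["SN"] in jmap.original_lengths
    ]
    pg = {"ID": "splicelift", "PN": "splicelift"}
    if pg_args:
        pg["CL"] = pg_args
    existing = d.get("PG", [])
    if existing:
        pg["PP"] = existing[-1]["ID"]
    d.setdefault("PG", []).append(pg)
    return pysam.AlignmentHeader.from_dict(d)


def _drop_as_artifact(rec: AlignmentRecord) -> AlignmentRecord:
    out = rec.copy()
    out.flag |= FLAG_UNMAPPED
    out.flag &= ~(FLAG_PROPER | FLAG_REVERSE)
    out.rname, out.pos, out.mapq = "*", 0, 0
    out.cigar = []
    out.set_tag(SPACER_TAG, "Z", "spacer")
    return out


def translate_one(
    rec: AlignmentRecord, jmap: JunctionMap, restored_mapq: int = 60
) -> TranslationOutcome:
    """Translate a single record (no pairing): classify, project, repair MAPQ."""
    category, jrec = classify_alignment(rec, jmap)
    if category == "unmapped":
        return TranslationOutcome(rec.copy(), "unmapped_passthrough")
    if category == "genomic":
        return TranslationOutcome(rec.copy(), "genomic_passthrough")
    if category == "spacer":
        return TranslationOutcome(_drop_as_artifact(rec), "dropped_unmappable")
    translated = translate_record(rec, jrec)
    n_gaps = sum(1 for _, op in translated.cigar if op == "N") - sum(
        1 for _, op in rec.cigar if op == "N"
    )
    translated = repair_mapq(
        translated, decode_alt_hits(translated), jmap, restored_mapq
    )
    return TranslationOutcome(translated, "junction_translated", n_gaps)


def translate_stream(
    in_path: str | Path,
    jmap: JunctionMap,
    out_path: str | Path,
    restored_mapq: int = 60,
    max_span: int = 1_000_000,
    summary_path: str | Path | None = None,
    pg_args: str | None = None,
) -> TranslationSummary:
    """Translate a SAM/BAM stream against a junction map.

    Input may be in any order: primary paired records are buffered by read
    name and re-paired when the mate appears; secondary and supplementary
    records are translated independently and never used for pair repair.
    The output header carries the original chromosome lengths and an
    appended @PG line.  ``'-'`` means stdin/stdout.
    """
    summary = TranslationSummary()
    in_path, out_path = str(in_path), str(out_path)
    write_mode = "wb" if out_path.endswith(".bam") else "wh"

    with pysam.AlignmentFile(in_path, check_sq=False) as infile:
        _check_header(infile.header, jmap)
        out_header = _genomic_header(infile.header, jmap, pg_args)
        pending: dict[str, TranslationOutcome] = {}

        def emit(outfile: pysam.AlignmentFile, rec: AlignmentRecord) -> None:
            outfile.write(
                pysam.AlignedSegment.fromstring(rec.to_sam_line(), out_header)
            )

        with pysam.AlignmentFile(out_path, write_mode, header=out_header) as outfile:
            for seg in infile:
                rec = AlignmentRecord.from_sam_line(seg.to_string())
                outcome = translate_one(rec, jmap, restored_mapq)
                summary.add(outcome)
                if not (rec.is_paired and rec.is_primary):
                    emit(outfile, outcome.record)
                    continue
                mate = pending.pop(rec.qname, None)
                if mate is None:
                    pending[rec.qname] = outcome
                    continue
                a, b = repair_pair(mate.record, outcome.record, max_span)
                emit(outfile, a)
                emit(outfile, b)
            for outcome in pending.values():
                emit(outfile, outcome.record)

    if summary_path is not None:
        summary.write_tsv(summary_path)
    log.info("translation summary: %s", summary.counts)
    return summary
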