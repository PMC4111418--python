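"""Transcript models and annotated exon-exon junctions.

RNA-seq reads frequently span splice boundaries, so the first step of an
annotation-based spliced alignment protocol is to know where those
boundaries are.  This module parses exon features from a GTF (or
GFF3-attribute-style) annotation into per-transcript exon chains and
enumerates the exon-exon junctions those chains imply.

Coordinate conventions: GTF is 1-based inclusive on disk; everything in
memory is 0-based half-open; SAM positions are emitted 1-based at the
output boundary.  The conversion is bijective, so parsing and
re-serialising an exon reproduces the file coordinates exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

__all__ = [
    "ExonInterval",
    "TranscriptModel",
    "Junction",
    "GtfParseError",
    "AnnotationValidationError",
    "parse_gtf",
    "enumerate_junctions",
]


class GtfParseError(ValueError):
    """A GTF line could not be parsed (message names the line number)."""


class AnnotationValidationError(ValueError):
    """A structurally valid file described an invalid transcript model."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """One exon as a genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationValidationError(
                f"negative coordinate in exon {self.chrom}:{self.start}-{self.end}"
            )
        if self.start >= self.end:
            raise AnnotationValidationError(
                f"empty or inverted exon {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_gtf_coords(self) -> tuple[int, int]:
        """Back to 1-based inclusive (start, end) as written in GTF."""
        return self.start + 1, self.end


@dataclass
class TranscriptModel:
    """A transcript: an ordered, non-overlapping exon chain on one strand.

    Exons are stored sorted by ascending genomic start regardless of
    strand; minus-strand transcripts are therefore stored in reverse
    transcription order, which keeps all downstream interval arithmetic
    strand-free.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonInterval] = field(default_factory=list)

    def validate(self) -> "TranscriptModel":
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: exon on {exon.chrom}, "
                    f"transcript on {self.chrom}"
                )
        self.exons.sort(key=lambda e: (e.start, e.end))
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start < left.end:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{left.start}-{left.end} and {right.start}-{right.end}"
                )
        return self

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Concatenated exon sequence on the genomic forward strand."""
        chrom_seq = genome[self.chrom]
        return "".join(chrom_seq[e.start:e.end] for e in self.exons)


@dataclass(frozen=True)
class Junction:
    """One exon-exon boundary: donor exon end and acceptor exon start.

    Identity is the splice-site pair on the chromosome, never the
    transcript: transcripts sharing a junction are merged, their ids kept
    as provenance only.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    transcript_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.donor_end > self.acceptor_start:
            raise AnnotationValidationError(
                f"junction {self.chrom}:{self.donor_end}-{self.acceptor_start}: "
                "donor end after acceptor start"
            )

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor_end, self.acceptor_start)


def _iter_exon_features(path: Path, attribute_dialect: str) -> Iterator[tuple[int, object]]:
    from gffutils import constants

    dialect_hint = None
    if attribute_dialect in ("gff3", "gtf"):
        dialect_hint = dict(constants.dialect)
        dialect_hint["fmt"] = attribute_dialect
        if attribute_dialect == "gff3":
            dialect_hint.update(
                {"keyval separator": "=", "quoted GFF2 values": False,
                 "trailing semicolon": False}
            )
    elif attribute_dialect != "auto":
        raise ValueError(f"unknown attribute_dialect {attribute_dialect!r}")

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-delimited columns, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                feature = feature_from_line(line, dialect=dialect_hint)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            yield lineno, feature


def parse_gtf(path: str | Path, attribute_dialect: str = "auto") -> list[TranscriptModel]:
    """Parse exon features from a GTF/GFF annotation into transcript models.

    Parameters
    ----------
    path
        Tab-delimited 9-column annotation file.  Lines starting with ``#``
        and non-``exon`` features are ignored.
    attribute_dialect
        ``"gtf"`` for ``key "value";`` attributes, ``"gff3"`` for
        ``key=value``, or ``"auto"`` (default) to detect per line.

    Returns
    -------
    One validated :class:`TranscriptModel` per distinct ``transcript_id``,
    exons sorted by ascending genomic start regardless of file order.
    """
    path = Path(path)
    models: dict[str, TranscriptModel] = {}
    for lineno, feat in _iter_exon_features(path, attribute_dialect):
        attrs = feat.attributes
        tids = attrs.get("transcript_id") or attrs.get("Parent")
        if not tids:
            raise GtfParseError(
                f"{path}:{lineno}: exon feature missing transcript_id attribute"
            )
        tid = tids[0]
        gids = attrs.get("gene_id") or attrs.get("ID") or [tid]
        gid = gids[0]
        # GTF start is 1-based inclusive; feature.start already carries it.
        exon = ExonInterval(chrom=feat.seqid, start=feat.start - 1, end=feat.end)
        model = models.get(tid)
        if model is None:
            models[tid] = model = TranscriptModel(
                transcript_id=tid, gene_id=gid, chrom=feat.seqid, strand=feat.strand
            )
        model.exons.append(exon)
    for model in models.values():
        model.validate()
    log.info("parsed %d transcript models from %s", len(models), path)
    return list(models.values())


def enumerate_junctions(models: Iterable[TranscriptModel]) -> list[Junction]:
    """Enumerate all distinct exon-exon junctions implied by the models.

    Each transcript with *k* exons contributes its *k - 1* adjacent exon
    pairs.  Junctions identical in (chrom, donor_end, acceptor_start) are
    merged with unioned transcript ids.  Abutting exon pairs (zero-length
    intron) carry no junction and are skipped with a warning.
    """
    merged: dict[tuple[str, int, int], set[str]] = {}
    n_abutting = 0
    for model in models:
        for left, right in zip(model.exons, model.exons[1:]):
            if left.end == right.start:
                n_abutting += 1
                log.warning(
                    "transcript %s: abutting exons at %s:%d carry no junction; skipped",
                    model.transcript_id, model.chrom, left.end,
                )
                continue
            merged.setdefault((model.chrom, left.end, right.start), set()).add(
                model.transcript_id
            )
    junctions = [
        Junction(chrom=c, donor_end=d, acceptor_start=a, transcript_ids=frozenset(tids))
        for (c, d, a), tids in sorted(merged.items())
    ]
    log.info(
        "enumerated %d distinct junctions (%d abutting pairs skipped)",
        len(junctions), n_abutting,
    )
    return junctions
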