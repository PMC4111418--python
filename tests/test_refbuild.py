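"""Extended-reference construction, junction map persistence, flank sizing."""

import pytest
from hypothesis import given, strategies as st

from splicelift.annotation import ExonInterval, Junction, TranscriptModel
from splicelift.refbuild import (
    JunctionMapFormatError,
    ReferenceBuildError,
    build_extended_reference,
    build_junction_blocks,
    flank_length,
    read_junction_map,
    write_extended_fasta,
    write_junction_map,
)

from conftest import random_sequence


class TestFlankLength:
    @pytest.mark.parametrize(
        "read_length,min_overhang,expected",
        [(100, 1, 99), (50, 1, 49), (100, 6, 94), (2, 1, 1)],
    )
    def test_values(self, read_length, min_overhang, expected):
        assert flank_length(read_length, min_overhang) == expected

    @pytest.mark.parametrize("read_length,min_overhang", [(100, 100), (100, 0), (1, 1)])
    def test_invalid_parameters(self, read_length, min_overhang):
        with pytest.raises(ReferenceBuildError):
            flank_length(read_length, min_overhang)


class TestBuildJunctionBlocks:
    def test_both_neighbors_longer_than_flank(self, three_exon_transcript):
        j = Junction("chr1", 400, 500)
        blocks = build_junction_blocks(j, three_exon_transcript, flank=49)
        assert [(b.start, b.end) for b in blocks] == [(351, 400), (500, 549)]

    def test_flank_crosses_short_exon(self, short_exon_transcript):
        """The 10-base middle exon forces the left flank into the first exon."""
        j = Junction("chr1", 310, 500)
        blocks = build_junction_blocks(j, short_exon_transcript, flank=49)
        assert [(b.start, b.end) for b in blocks] == [(161, 200), (300, 310), (500, 549)]

    def test_flank_truncated_at_transcript_start(self):
        tx = TranscriptModel(
            "T1", "G1", "chr1", "+",
            [ExonInterval("chr1", 0, 20), ExonInterval("chr1", 500, 700)],
        ).validate()
        blocks = build_junction_blocks(Junction("chr1", 20, 500), tx, flank=49)
        assert [(b.start, b.end) for b in blocks] == [(0, 20), (500, 549)]

    def test_flank_accumulation_matches_transcript_coordinate_oracle(
        self, short_exon_transcript
    ):
        """Blocks cover exactly the spliced positions within `flank` of the boundary.

        Oracle: enumerate the transcript's per-base genomic coordinates, find
        the boundary's spliced position, and take the flank window there.
        """
        tx = short_exon_transcript
        per_base = [g for e in tx.exons for g in range(e.start, e.end)]
        for junction, flank in [
            (Junction("chr1", 200, 300), 49),
            (Junction("chr1", 310, 500), 49),
            (Junction("chr1", 310, 500), 15),
            (Junction("chr1", 200, 300), 250),
        ]:
            donor_tpos = per_base.index(junction.donor_end - 1) + 1
            expected = set(
                per_base[max(0, donor_tpos - flank): donor_tpos + flank]
            )
            blocks = build_junction_blocks(junction, tx, flank)
            covered = {g for b in blocks for g in range(b.start, b.end)}
            assert covered == expected

    def test_junction_not_in_transcript_rejected(self, three_exon_transcript):
        with pytest.raises(ReferenceBuildError, match="not an adjacent exon pair"):
            build_junction_blocks(Junction("chr1", 123, 456), three_exon_transcript, 49)


@pytest.fixture
def toy_reference(toy_genome, three_exon_transcript, short_exon_transcript):
    return build_extended_reference(
        toy_genome, [three_exon_transcript, short_exon_transcript],
        read_length=50, min_overhang=1, spacer=100,
    )


class TestBuildExtendedReference:
    def test_single_junction_placement_arithmetic(self, toy_genome):
        tx = TranscriptModel(
            "T1", "G1", "chr1", "+",
            [ExonInterval("chr1", 100, 1000), ExonInterval("chr1", 2000, 3000)],
        ).validate()
        ref = build_extended_reference(
            toy_genome, [tx], read_length=50, spacer=100
        )
        (rec,) = ref.records
        assert rec.ext_start == 10_100
        assert rec.length == 98
        assert len(ref.sequences["chr1"]) == 10_000 + 100 + 98

    def test_genomic_prefix_identical(self, toy_reference, toy_genome):
        ext = toy_reference.sequences["chr1"]
        assert ext[:10_000] == toy_genome["chr1"]

    def test_junction_sequence_content_property(self, toy_reference, toy_genome):
        """Every junction substring equals the concatenation of its block substrings."""
        ext = toy_reference.sequences["chr1"]
        for rec in toy_reference.records:
            expected = "".join(
                toy_genome["chr1"][b.start:b.end] for b in rec.blocks
            )
            assert ext[rec.ext_start:rec.ext_start + rec.length] == expected

    def test_spacer_regions_are_all_N(self, toy_reference):
        ext = toy_reference.sequences["chr1"]
        jmap = toy_reference.junction_map
        cursor = jmap.original_lengths["chr1"]
        for rec in jmap.records_for("chr1"):
            assert ext[cursor:rec.ext_start] == "N" * jmap.spacer
            cursor = rec.ext_end

    def test_shared_block_tuple_deduplicated(self, toy_genome, three_exon_transcript):
        """Two transcripts producing identical block tuples emit one sequence."""
        twin = TranscriptModel(
            "T1b", "G1", "chr1", "+", list(three_exon_transcript.exons)
        ).validate()
        ref = build_extended_reference(
            toy_genome, [three_exon_transcript, twin], read_length=50
        )
        assert len(ref.records) == 2  # two junctions, each deduplicated
        for rec in ref.records:
            assert rec.transcript_ids == ("T1", "T1b")

    def test_same_splice_site_different_neighborhood_kept_separate(
        self, toy_genome, toy_reference, short_exon_transcript
    ):
        """T1 and T2 share junction (200,300) but T2's right flank crosses its
        short exon, so two distinct junction sequences must exist — and each
        must project its own bases correctly (per-base content check)."""
        shared = [
            r for r in toy_reference.records
            if r.junction_id.split(".")[0] == "chr1:200-300"
        ]
        assert len(shared) == 2
        block_tuples = {tuple((b.start, b.end) for b in r.blocks) for r in shared}
        assert block_tuples == {
            ((151, 200), (300, 349)),              # T1: both flanks in long exons
            ((151, 200), (300, 310), (500, 539)),  # T2: flank crosses the short exon
        }
        ext = toy_reference.sequences["chr1"]
        for rec in shared:
            offset = rec.ext_start
            for b in rec.blocks:
                for g in range(b.start, b.end):
                    assert ext[offset] == toy_genome["chr1"][g]
                    offset += 1

    def test_unknown_chromosome_rejected(self, three_exon_transcript):
        with pytest.raises(ReferenceBuildError, match="absent from genome"):
            build_extended_reference(
                {"chrX": "ACGT" * 300}, [three_exon_transcript], read_length=50
            )

    def test_junction_past_chromosome_end_rejected(self, three_exon_transcript):
        with pytest.raises(ReferenceBuildError):
            build_extended_reference(
                {"chr1": random_sequence(600, seed=3)},
                [three_exon_transcript], read_length=50,
            )


class TestFlankWindowProperty:
    def test_no_read_length_window_fits_in_one_block(self, small_extended):
        """With full flanks no read-length window of a junction sequence lies
        within a single block, so unspliced reads cannot align there."""
        L = small_extended.read_length
        assert small_extended.flank < L
        for rec in small_extended.records:
            cuts = []
            acc = 0
            for b in rec.blocks[:-1]:
                acc += b.length
                cuts.append(acc)
            for start in range(rec.length - L + 1):
                assert any(start < cut < start + L for cut in cuts), (
                    f"window at {start} of {rec.junction_id} sits in one block"
                )


class TestPersistence:
    def test_map_roundtrip_identity(self, toy_reference, tmp_path):
        path = tmp_path / "ref.jmap"
        write_junction_map(toy_reference, path)
        loaded = read_junction_map(path)
        assert loaded.read_length == toy_reference.read_length
        assert loaded.flank == toy_reference.flank
        assert loaded.spacer == toy_reference.spacer
        assert loaded.original_lengths == toy_reference.original_lengths
        assert loaded.records == toy_reference.junction_map.records

    def test_empty_map_roundtrip(self, toy_genome, tmp_path):
        ref = build_extended_reference(toy_genome, [], read_length=50)
        path = tmp_path / "empty.jmap"
        write_junction_map(ref, path)
        assert read_junction_map(path).records == []

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "x.jmap"
        path.write_text("not a map\n")
        with pytest.raises(JunctionMapFormatError, match="magic"):
            read_junction_map(path)

    def test_truncated_header_rejected(self, tmp_path):
        path = tmp_path / "x.jmap"
        path.write_text("#splicelift-jmap\tv1\n#read_length\t100\n")
        with pytest.raises(JunctionMapFormatError, match="truncated|incomplete"):
            read_junction_map(path)

    def test_ext_start_inside_genome_rejected_on_load(self, toy_reference, tmp_path):
        path = tmp_path / "bad.jmap"
        write_junction_map(toy_reference, path)
        lines = path.read_text().splitlines()
        body = next(i for i, l in enumerate(lines) if not l.startswith("#"))
        fields = lines[body].split("\t")
        fields[2] = "5"  # ext_start within the genomic sequence
        lines[body] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(JunctionMapFormatError, match="within the genomic"):
            read_junction_map(path)

    def test_fasta_roundtrip_and_line_width(self, toy_reference, tmp_path):
        path = tmp_path / "ext.fa"
        write_extended_fasta(toy_reference, path, line_width=60)
        lines = path.read_text().splitlines()
        assert lines[0] == ">chr1"
        assert all(len(l) <= 60 for l in lines[1:])
        seq = "".join(l for l in lines[1:] if not l.startswith(">"))
        assert seq == toy_reference.sequences["chr1"]

    def test_build_and_write_deterministic(
        self, toy_genome, three_exon_transcript, short_exon_transcript, tmp_path
    ):
        outputs = []
        for run in ("a", "b"):
            ref = build_extended_reference(
                toy_genome, [short_exon_transcript, three_exon_transcript],
                read_length=50,
            )
            fa, jm = tmp_path / f"{run}.fa", tmp_path / f"{run}.jmap"
            write_extended_fasta(ref, fa)
            write_junction_map(ref, jm)
            outputs.append((fa.read_bytes(), jm.read_bytes()))
        assert outputs[0] == outputs[1]


@given(
    st.lists(
        st.tuples(st.integers(1, 300), st.integers(1, 500)),
        min_size=2, max_size=8,
    ),
    st.integers(2, 120),
)
def test_block_coverage_never_exceeds_two_flanks(exon_intron_lengths, read_length):
    """Property: total junction-sequence length is at most 2*flank and every
    block is contained in an exon of the transcript."""
    exons = []
    cursor = 0
    for elen, ilen in exon_intron_lengths:
        exons.append(ExonInterval("chr1", cursor, cursor + elen))
        cursor += elen + ilen
    tx = TranscriptModel("T", "G", "chr1", "+", exons).validate()
    flank = read_length - 1
    j = Junction("chr1", exons[0].end, exons[1].start)
    blocks = build_junction_blocks(j, tx, flank)
    assert sum(b.length for b in blocks) <= 2 * flank
    for b in blocks:
        assert any(e.start <= b.start and b.end <= e.end for e in exons)
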