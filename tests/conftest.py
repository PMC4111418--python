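import numpy as np
import pytest
from hypothesis import settings

from splicelift.annotation import ExonInterval, TranscriptModel
from splicelift.fixtures import ScenarioParams, make_scenario
from splicelift.refbuild import build_extended_reference

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length).tobytes().decode()


@pytest.fixture(scope="session")
def toy_genome():
    """One 10 kb chromosome with a fixed random sequence."""
    return {"chr1": random_sequence(10_000, seed=42)}


@pytest.fixture(scope="session")
def three_exon_transcript():
    """Plus-strand transcript with exons [0,200), [300,400), [500,700)."""
    return TranscriptModel(
        transcript_id="T1", gene_id="G1", chrom="chr1", strand="+",
        exons=[
            ExonInterval("chr1", 0, 200),
            ExonInterval("chr1", 300, 400),
            ExonInterval("chr1", 500, 700),
        ],
    ).validate()


@pytest.fixture(scope="session")
def short_exon_transcript():
    """Transcript with a 10-base middle exon, shorter than typical flanks."""
    return TranscriptModel(
        transcript_id="T2", gene_id="G2", chrom="chr1", strand="+",
        exons=[
            ExonInterval("chr1", 0, 200),
            ExonInterval("chr1", 300, 310),
            ExonInterval("chr1", 500, 700),
        ],
    ).validate()


@pytest.fixture(scope="session")
def small_scenario():
    """A compact seeded scenario shared by read-level tests."""
    return make_scenario(ScenarioParams(n_reads=500), seed=11)


@pytest.fixture(scope="session")
def small_extended(small_scenario):
    return build_extended_reference(
        small_scenario.genome, small_scenario.transcripts,
        read_length=small_scenario.read_length,
    )


def project_cigar_per_base(pos_1based: int, cigar) -> list[int]:
    """Expand a (possibly N-gapped) CIGAR into per-aligned-base 0-based coords."""
    coords: list[int] = []
    ref = pos_1based - 1
    for n, op in cigar:
        if op in "M=X":
            coords.extend(range(ref, ref + n))
            ref += n
        elif op in "DN":
            ref += n
    return coords
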