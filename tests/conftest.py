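"""Shared fixtures: tiny hand-checkable objects and one synthetic bundle."""

import pytest

from mencrna.ccv import Variant
from mencrna.genes import GeneModel, Transcript
from mencrna.intervals import CaptureUniverse, GenomicInterval
from mencrna.simulate import SimConfig, simulate_genome, simulate_signals


@pytest.fixture
def toy_universe() -> CaptureUniverse:
    return CaptureUniverse([GenomicInterval("chr1", 0, 1000)])


@pytest.fixture
def two_exon_gene() -> GeneModel:
    """+ strand transcript: exons chr1:1000-1100 and chr1:1200-1300."""
    t = Transcript(
        "t1",
        "g1",
        (
            GenomicInterval("chr1", 1000, 1100, "+"),
            GenomicInterval("chr1", 1200, 1300, "+"),
        ),
    )
    return GeneModel("g1", [t], "mencRNA")


@pytest.fixture
def minus_gene() -> GeneModel:
    t = Transcript(
        "t2",
        "g2",
        (
            GenomicInterval("chr1", 1000, 1100, "-"),
            GenomicInterval("chr1", 1200, 1300, "-"),
        ),
    )
    return GeneModel("g2", [t], "mencRNA")


@pytest.fixture(scope="session")
def default_genome():
    cfg = SimConfig(seed=12345)
    return cfg, simulate_genome(cfg)


@pytest.fixture(scope="session")
def default_signals(default_genome):
    cfg, genome = default_genome
    signals, manifest = simulate_signals(cfg, genome)
    return signals, manifest


def variant(pos: int, p: float = 1e-8, vid: str | None = None, chrom: str = "chr1") -> Variant:
    return Variant(vid or f"v{pos}", chrom, pos, p)
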