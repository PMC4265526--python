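import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from readdist.io import AlignedRead, PairRecord, Placement, Read
from readdist.simulate import (PairSample, SimulationConfig, make_six_subsets,
                               random_genome, sample_reads)


def make_read(seq: str, rid: str = "r") -> Read:
    return Read(id=rid, seq=seq)


def make_aligned(rid: str, seq: str, start: int, end: int,
                 ref: str = "chr1", strand: str = "+") -> AlignedRead:
    return AlignedRead(read=Read(id=rid, seq=seq),
                       placements=(Placement(ref, start, end, strand),))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def build_sample(d1, d2, target="bt", predictor="af", label="T") -> PairSample:
    """A PairSample whose target/predictor columns are the given values."""
    reads = {}
    pairs = []
    for i, (a, b) in enumerate(zip(d1, d2)):
        ids = (f"p{i}x", f"p{i}y")
        for rid in ids:
            reads[rid] = make_aligned(rid, "ACGT", 0, 4)
        pairs.append(PairRecord(id1=ids[0], id2=ids[1],
                                **{target: float(a), predictor: float(b)}))
    return PairSample(label=label, pairs=tuple(pairs), reads=reads)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, small rendition of the simulated experiment."""
    return SimulationConfig(genome_length=8_000, n_reads=300, n_pairs=1_000,
                            read_length_mean=100, read_length_sd=6, seed=7)


@pytest.fixture(scope="session")
def small_reads(small_config):
    genome = random_genome(small_config.genome_length, small_config.seed)
    return genome, sample_reads(genome, small_config)


@pytest.fixture(scope="session")
def small_subsets(small_config, small_reads):
    _, reads = small_reads
    return make_six_subsets(reads, small_config)
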