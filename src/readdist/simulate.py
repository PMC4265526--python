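"""Synthetic reference, reads and controlled-overlap pair samples.

The generator emulates the structure of the experimental read sets:
fixed-length-ish reads sampled uniformly from a single reference
chromosome, a reverse-complemented copy of every read (so strand
orientation is unknown to sequence-based distances, as it is for real
assembly input), and pair samples in which exactly half of the pairs
have zero placement overlap and the other half span the whole range of
overlap degrees.

Sequencing error is deliberately not modeled; reads are exact substrings
(or their reverse complements) of the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (AlignedRead, PairRecord, Placement, Read,
                 reverse_complement, write_pairs)

logger = logging.getLogger(__name__)

#: Reads shorter than the tetramer window are unusable downstream.
MIN_READ_LENGTH = 4

SUBSET_LABELS = "ABCDEF"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults are a desk-scale rendition of the short-read setting:
    a 50 kb single-chromosome reference, 2,000 sampled reads of
    100 ± 6 bp (doubled to 4,000 by reverse complementation), six pair
    subsets of 20,000 pairs each, half of them non-overlapping.
    """

    genome_length: int = 50_000
    read_length_mean: float = 100.0
    read_length_sd: float = 6.0
    n_reads: int = 2_000           # rs: forward reads before rev-comping
    n_pairs: int = 20_000          # rp: pairs per subset
    n_subsets: int = 6
    overlap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < MIN_READ_LENGTH:
            raise ValueError("genome_length too small")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.read_length_sd < 0:
            raise ValueError("read_length_sd must be non-negative")


@dataclass(frozen=True)
class PairSample:
    """A labelled sample of read pairs plus the reads they refer to."""

    label: str
    pairs: tuple[PairRecord, ...]
    reads: dict[str, AlignedRead]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            if p.id1 not in self.reads or p.id2 not in self.reads:
                raise ValueError(
                    f"pair ({p.id1}, {p.id2}) references unknown read")
            key = frozenset((p.id1, p.id2))
            if key in seen:
                raise ValueError(f"duplicated pair ({p.id1}, {p.id2})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)


def random_genome(length: int, seed: int, ref_id: str = "chr1") -> Read:
    """I.i.d. uniform A/C/G/T reference sequence of the given length."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=length).tobytes().decode("ascii")
    return Read(id=ref_id, seq=seq)


def sample_reads(genome: Read,
                 config: SimulationConfig) -> list[AlignedRead]:
    """Draw rs forward reads and add a reverse-complemented copy of each.

    Read lengths are rounded draws from Normal(mean, sd), clipped to
    [4, genome_length]; start positions are uniform. Each reverse copy
    carries the SAME placement as its forward partner with strand '-'
    (it covers the same reference interval), so the total is 2·rs reads
    each with exactly one truth placement.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rs = config.n_reads
    glen = len(genome)
    lengths = np.rint(rng.normal(config.read_length_mean,
                                 config.read_length_sd, size=rs))
    lengths = np.clip(lengths, MIN_READ_LENGTH, glen).astype(int)
    starts = rng.integers(0, glen - lengths + 1)
    width = len(str(rs - 1)) if rs > 1 else 1
    out: list[AlignedRead] = []
    for i, (start, length) in enumerate(zip(starts, lengths)):
        sub = genome.seq[start:start + length]
        fwd_id = f"r{i:0{width}d}"
        fwd = AlignedRead(
            read=Read(id=fwd_id, seq=sub),
            placements=(Placement(genome.id, int(start),
                                  int(start + length), "+"),))
        rev = AlignedRead(
            read=Read(id=fwd_id + "_rc", seq=reverse_complement(sub)),
            placements=(Placement(genome.id, int(start),
                                  int(start + length), "-"),))
        out.extend((fwd, rev))
    return out


def _placement_arrays(reads: Sequence[AlignedRead]):
    ref = np.array([r.placements[0].ref_id for r in reads])
    start = np.array([r.placements[0].start for r in reads])
    end = np.array([r.placements[0].end for r in reads])
    strand = np.array([r.placements[0].strand for r in reads])
    return ref, start, end, strand


N_OVERLAP_STRATA = 10


def sample_pairs(reads: Sequence[AlignedRead], rp: int,
                 overlap_fraction: float, seed: int,
                 label: str = "A") -> PairSample:
    """Draw rp distinct unordered read pairs with a controlled class mix.

    Exactly round(rp·overlap_fraction) pairs have placements overlapping
    by at least one reference base; the rest have zero overlap. The
    overlapping half is drawn in 10 equal strata of target overlap
    degree (fraction of the shorter read covered by the intersection),
    accepting the available pair whose degree is nearest the target, so
    that the achieved degrees spread over the whole (0, 1] range.

    Overlapping pairs are drawn strand-concordant (both reads as
    sequenced from the same strand). Every overlapping genomic
    configuration is still represented — each read's reverse-complement
    twin is in the pool — but the target distance stays identifiable
    from the raw sequences, which is the premise of the prediction task.
    """
    if any(len(r.placements) != 1 for r in reads):
        raise ValueError("sample_pairs expects single-placement truth reads")
    rng = np.random.default_rng(seed)
    n = len(reads)
    n_ov = int(round(rp * overlap_fraction))
    n_dis = rp - n_ov
    ref, start, end, strand = _placement_arrays(reads)
    length = end - start
    chosen: set[frozenset] = set()
    pairs: list[tuple[int, int]] = []

    def register(i: int, j: int) -> bool:
        key = frozenset((int(i), int(j)))
        if key in chosen:
            return False
        chosen.add(key)
        pairs.append((int(i), int(j)))
        return True

    # --- overlapping half, stratified by target overlap degree ---
    max_attempts = 200 * max(n_ov, 1)
    attempts = 0
    s = 0
    drawn = 0
    while drawn < n_ov:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "insufficient distinct overlapping pairs available "
                f"(drew {drawn} of {n_ov})")
        target = rng.uniform(s / N_OVERLAP_STRATA, (s + 1) / N_OVERLAP_STRATA)
        i = int(rng.integers(n))
        ov = np.minimum(end, end[i]) - np.maximum(start, start[i])
        cand = np.flatnonzero((ref == ref[i]) & (strand == strand[i])
                              & (ov > 0))
        cand = cand[cand != i]
        if cand.size == 0:
            continue
        degree = ov[cand] / np.minimum(length[cand], length[i])
        for j in cand[np.argsort(np.abs(degree - target))]:
            if register(i, j):
                drawn += 1
                s = (s + 1) % N_OVERLAP_STRATA
                break

    # --- non-overlapping half, rejection sampling ---
    max_attempts = 200 * max(n_dis, 1)
    attempts = 0
    drawn = 0
    while drawn < n_dis:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "insufficient distinct non-overlapping pairs available "
                f"(drew {drawn} of {n_dis})")
        i, j = rng.integers(n, size=2)
        if i == j:
            continue
        disjoint = (ref[i] != ref[j] or end[i] <= start[j]
                    or end[j] <= start[i])
        if disjoint and register(i, j):
            drawn += 1

    order = rng.permutation(len(pairs))
    records = tuple(PairRecord(id1=reads[pairs[o][0]].id,
                               id2=reads[pairs[o][1]].id)
                    for o in order)
    used = {rid for p in records for rid in (p.id1, p.id2)}
    return PairSample(label=label, pairs=records,
                      reads={r.id: r for r in reads if r.id in used})


def make_six_subsets(reads: Sequence[AlignedRead],
                     config: SimulationConfig) -> list[PairSample]:
    """Draw ``config.n_subsets`` pair samples with labels A, B, C, ...

    Subset seeds are derived deterministically from ``config.seed``;
    pairs may recur across subsets (only within-subset uniqueness is
    required) and the pairwise overlap is logged.
    """
    n = config.n_subsets
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    seeds = rng.integers(0, 2**31 - 1, size=n)
    labels = [SUBSET_LABELS[i] if i < len(SUBSET_LABELS) else f"S{i}"
              for i in range(n)]
    samples = [sample_pairs(reads, config.n_pairs, config.overlap_fraction,
                            seed=int(seeds[i]), label=labels[i])
               for i in range(n)]
    for a, b in combinations(samples, 2):
        keys_a = {frozenset((p.id1, p.id2)) for p in a.pairs}
        shared = sum(frozenset((p.id1, p.id2)) in keys_a for p in b.pairs)
        logger.info("subsets %s/%s share %d pairs", a.label, b.label, shared)
    return samples


def simulate_experiment(config: SimulationConfig
                        ) -> tuple[Read, list[AlignedRead],
                                   list[PairSample]]:
    """Genome → reads → pair subsets, all from one seed."""
    genome = random_genome(config.genome_length, config.seed)
    reads = sample_reads(genome, config)
    samples = make_six_subsets(reads, config)
    return genome, reads, samples


# ---------------------------------------------------------------------------
# emission of the standard formats, so the truth can round-trip

def write_genome_fasta(genome: Read, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome.seq[i:i + 70] + "\n")


def write_reads_fastq(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """Reads as FASTQ with uniform dummy qualities ('I')."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.read.seq}\n+\n{'I' * len(r.read)}\n")


def write_truth_sam(reads: Sequence[AlignedRead], genome: Read,
                    path: str | Path) -> None:
    """Truth placements as SAM (SEQ follows the forward reference strand)."""
    import pysam

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome.id, "LN": len(genome)}],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            for p in r.placements:
                seg = pysam.AlignedSegment(header)
                seg.query_name = r.id
                seq = r.read.seq
                if p.strand == "-":
                    seq = reverse_complement(seq)
                seg.query_sequence = seq
                seg.flag = 16 if p.strand == "-" else 0
                seg.reference_id = 0
                seg.reference_start = p.start
                seg.mapping_quality = 255
                seg.cigarstring = f"{len(r.read)}M"
                seg.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(r.read))
                out.write(seg)


def write_sample_tsv(sample: PairSample, path: str | Path) -> None:
    write_pairs(sample.pairs, path)
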