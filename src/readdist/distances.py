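"""The four read-pair distances, each normalized to [0, 1].

* ``af`` — alignment-free: Euclidean distance between tetramer
  relative-frequency vectors (sliding window of length k=4).
* ``nw`` — global (Needleman-Wunsch) alignment score with +1/-1/-1
  scoring, turned into a distance against the per-pair score bounds.
* ``bl`` — word-seeded local alignment score (a self-contained stand-in
  for pairwise blastn with word size 4 and masking off), normalized by
  the maximum achievable local score.
* ``bt`` — the overlap-based target distance, computed from reference
  placements: 1 - 2·∇/(λ1+λ2), where ∇ is the number of reference
  positions covered by both reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .io import AlignedRead, Read

logger = logging.getLogger(__name__)

#: Base → 2-bit code in lexicographic order; 255 marks ambiguity.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

DEFAULT_K = 4
DEFAULT_WORD_SIZE = 4
MATCH, MISMATCH, GAP = 1, -1, -1


@dataclass(frozen=True)
class KmerVector:
    """Relative frequencies of the 4^k k-mers of one read.

    ``freqs`` is indexed by the lexicographic rank of the k-mer over
    (A, C, G, T); for k=4 it has 256 entries summing to 1. ``n_windows``
    counts the sliding windows that contained no ambiguous base.
    """

    k: int
    freqs: np.ndarray
    n_windows: int


@dataclass(frozen=True)
class AlignmentScore:
    """An alignment score with its per-pair attainable bounds."""

    score: int
    max_score: int
    min_score: int

    def __post_init__(self) -> None:
        if not self.min_score <= self.score <= self.max_score:
            raise ValueError(
                f"score {self.score} outside "
                f"[{self.min_score}, {self.max_score}]")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_ranks(seq: str, k: int = DEFAULT_K) -> np.ndarray:
    """Lexicographic ranks of the valid k-mer windows of ``seq``.

    Windows containing a non-ACGT character are dropped.
    """
    codes = _encode(seq)
    n = len(codes)
    if n < k:
        raise ValueError(f"sequence of length {n} shorter than k={k}")
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows != 255).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    return (windows[valid].astype(np.int64) * powers).sum(axis=1)


def kmer_frequency_vector(read: Read, k: int = DEFAULT_K) -> KmerVector:
    """Sliding-window k-mer relative-frequency vector of a read.

    The window runs from position 1 to n-k+1; each valid window
    contributes 1/n_windows to the rank of its k-mer. Ambiguous windows
    are excluded from the normalizing denominator.
    """
    ranks = kmer_ranks(read.seq, k)
    if ranks.size == 0:
        raise ValueError(
            f"read {read.id!r}: no unambiguous window of length {k}")
    counts = np.bincount(ranks, minlength=4 ** k)
    return KmerVector(k=k, freqs=counts / ranks.size, n_windows=ranks.size)


def af_distance(r1: Read, r2: Read, k: int = DEFAULT_K) -> float:
    """Euclidean distance between k-mer frequency vectors, scaled to [0,1].

    The raw Euclidean distance between two frequency vectors is at most
    √2 (two disjoint one-hot vectors), so dividing by √2 maps the
    distance onto [0, 1].
    """
    v1 = kmer_frequency_vector(r1, k)
    v2 = kmer_frequency_vector(r2, k)
    d = float(np.linalg.norm(v1.freqs - v2.freqs) / math.sqrt(2.0))
    return min(d, 1.0)  # guard against rounding a hair past the bound


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.gap_score = GAP  # uniform: internal and terminal gaps alike
    return aligner


_GLOBAL_ALIGNER = _aligner("global")
_LOCAL_ALIGNER = _aligner("local")


def nw_align(r1: Read, r2: Read) -> AlignmentScore:
    """Optimal global alignment score with +1 match, -1 mismatch, -1 gap.

    ``max_score`` is the best score attainable at these lengths
    (min(λ1,λ2) matches minus the unavoidable |λ1-λ2| length-difference
    gaps) and ``min_score`` the worst (-(λ1+λ2), everything gapped).
    """
    l1, l2 = len(r1), len(r2)
    if l1 == 0 or l2 == 0:
        raise ValueError("cannot align an empty read")
    score = int(_GLOBAL_ALIGNER.score(r1.seq, r2.seq))
    return AlignmentScore(score=score,
                          max_score=min(l1, l2) - abs(l1 - l2),
                          min_score=-(l1 + l2))


def nw_distance(r1: Read, r2: Read) -> float:
    """Global-alignment distance: (max_score - score)/(max_score - min_score).

    Zero iff the score attains its per-pair maximum (identical sequences
    when lengths are equal); always in [0, 1].
    """
    s = nw_align(r1, r2)
    return (s.max_score - s.score) / (s.max_score - s.min_score)


def _shares_word(r1: Read, r2: Read, word_size: int) -> bool:
    if len(r1) < word_size or len(r2) < word_size:
        return False
    w1 = set(map(int, kmer_ranks(r1.seq, word_size)))
    if not w1:
        return False
    w2 = set(map(int, kmer_ranks(r2.seq, word_size)))
    return not w1.isdisjoint(w2)


def local_align(r1: Read, r2: Read,
                word_size: int = DEFAULT_WORD_SIZE) -> AlignmentScore:
    """Best local alignment score seeded by an exact shared word.

    If the two reads share no exact word of ``word_size`` bases there is
    no seed and the score is 0; otherwise the optimal Smith-Waterman
    score under the +1/-1/-1 scheme is returned. No masking or
    low-complexity filtering is applied.
    """
    l1, l2 = len(r1), len(r2)
    if l1 == 0 or l2 == 0:
        raise ValueError("cannot align an empty read")
    if _shares_word(r1, r2, word_size):
        score = int(_LOCAL_ALIGNER.score(r1.seq, r2.seq))
    else:
        score = 0
    return AlignmentScore(score=score, max_score=min(l1, l2), min_score=0)


def bl_distance(r1: Read, r2: Read,
                word_size: int = DEFAULT_WORD_SIZE) -> float:
    """Local-alignment distance: (max_score - score)/max_score.

    1 when the reads share no seed word, 0 for identical reads.
    """
    s = local_align(r1, r2, word_size)
    return (s.max_score - s.score) / s.max_score


def _overlap(p1, p2) -> int:
    if p1.ref_id != p2.ref_id:
        return 0
    return max(0, min(p1.end, p2.end) - max(p1.start, p2.start))


def bt_distance(a1: AlignedRead, a2: AlignedRead) -> float:
    """Overlap-based target distance from reference placements.

    For single placements: 1 - 2·∇/(λ1+λ2) with ∇ the size of the
    intersection of the two placement intervals (0 when the references
    differ). With multiple placements the average over all placement
    combinations is used, in input order.
    """
    l1, l2 = len(a1.read), len(a2.read)
    values = [1.0 - 2.0 * _overlap(p1, p2) / (l1 + l2)
              for p1 in a1.placements for p2 in a2.placements]
    return float(np.mean(values))


DISTANCE_NAMES = ("bt", "nw", "bl", "af")


def compute_all_distances(sample, which: Sequence[str] = DISTANCE_NAMES,
                          k: int = DEFAULT_K,
                          word_size: int = DEFAULT_WORD_SIZE):
    """Populate the requested distances for every pair of a sample.

    Pairs whose computation fails (e.g. an all-N read for ``af``) are
    flagged: the failing distances stay ``None`` and a summary is
    logged. Returns a new sample of the same type.

    The tetramer vectors are precomputed per read, so ``af`` over a
    large sample is a vectorized matrix operation.
    """
    unknown = set(which) - set(DISTANCE_NAMES)
    if unknown:
        raise ValueError(f"unknown distance(s): {sorted(unknown)}")
    reads = sample.reads
    ids = list(reads)
    idx = {rid: i for i, rid in enumerate(ids)}

    af_matrix: Optional[np.ndarray] = None
    af_ok: Optional[np.ndarray] = None
    if "af" in which:
        af_matrix = np.zeros((len(ids), 4 ** k))
        af_ok = np.zeros(len(ids), dtype=bool)
        for i, rid in enumerate(ids):
            try:
                af_matrix[i] = kmer_frequency_vector(reads[rid].read, k).freqs
                af_ok[i] = True
            except ValueError:
                pass

    n_failed = 0
    out = []
    for pair in sample.pairs:
        i1, i2 = idx[pair.id1], idx[pair.id2]
        a1, a2 = reads[pair.id1], reads[pair.id2]
        updates: dict[str, Optional[float]] = {}
        failed = False
        if "bt" in which:
            updates["bt"] = bt_distance(a1, a2)
        if "nw" in which:
            try:
                updates["nw"] = nw_distance(a1.read, a2.read)
            except ValueError:
                failed = True
        if "bl" in which:
            try:
                updates["bl"] = bl_distance(a1.read, a2.read, word_size)
            except ValueError:
                failed = True
        if "af" in which:
            if af_ok[i1] and af_ok[i2]:
                d = np.linalg.norm(af_matrix[i1] - af_matrix[i2])
                updates["af"] = min(float(d / math.sqrt(2.0)), 1.0)
            else:
                failed = True
        n_failed += failed
        out.append(pair.with_distances(**updates))
    if n_failed:
        logger.warning("compute_all_distances: %d pair(s) flagged with "
                       "incomputable distances", n_failed)
    return replace(sample, pairs=tuple(out))
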