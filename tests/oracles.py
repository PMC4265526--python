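"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths and any alignment
library: alignment scores come from direct recursion over all global
alignments, k-mer frequencies from dictionary counting, and AUC from the
pairwise Mann-Whitney statistic.
"""

from functools import lru_cache

MATCH, MISMATCH, GAP = 1, -1, -1


def global_score(s1: str, s2: str) -> int:
    """Best global alignment score by recursion over all alignments."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(s1):
            return GAP * (len(s2) - j)
        if j == len(s2):
            return GAP * (len(s1) - i)
        sub = MATCH if s1[i] == s2[j] else MISMATCH
        return max(rec(i + 1, j + 1) + sub,
                   rec(i + 1, j) + GAP,
                   rec(i, j + 1) + GAP)

    return rec(0, 0)


def shares_word(s1: str, s2: str, w: int = 4) -> bool:
    words1 = {s1[i:i + w] for i in range(len(s1) - w + 1)}
    words2 = {s2[i:i + w] for i in range(len(s2) - w + 1)}
    return bool(words1 & words2)


def local_score(s1: str, s2: str, w: int = 4) -> int:
    """Exhaustive seeded local score: best global score over all
    non-empty substring pairs, 0 when no exact shared word exists."""
    if not shares_word(s1, s2, w):
        return 0
    best = 0
    for a in range(len(s1)):
        for b in range(a + 1, len(s1) + 1):
            for c in range(len(s2)):
                for d in range(c + 1, len(s2) + 1):
                    best = max(best, global_score(s1[a:b], s2[c:d]))
    return best


def kmer_freqs(seq: str, k: int = 4) -> dict[str, float]:
    counts: dict[str, int] = {}
    n_valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if any(c not in "ACGT" for c in window):
            continue
        n_valid += 1
        counts[window] = counts.get(window, 0) + 1
    return {w: c / n_valid for w, c in counts.items()}


def af(s1: str, s2: str, k: int = 4) -> float:
    f1, f2 = kmer_freqs(s1, k), kmer_freqs(s2, k)
    sq = sum((f1.get(w, 0.0) - f2.get(w, 0.0)) ** 2
             for w in set(f1) | set(f2))
    return (sq / 2.0) ** 0.5


def mann_whitney_auc(pos_scores, neg_scores) -> float:
    """P(random negative scores higher than random positive) + tie credit.

    With 'low predictor value means positive', this is the AUC of the
    threshold-rule ROC curve.
    """
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if n > p:
                wins += 1.0
            elif n == p:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
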