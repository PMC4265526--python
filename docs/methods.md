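# Methods

This note records the models, defaults and numerical choices behind
`readdist`, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

Overlap-graph approaches to assembly and read prefiltering need to know,
for pairs of reads, whether they cover a common stretch of the genome.
When reads can be placed on a reference, the overlap is directly
measurable; the question the package addresses is how well cheap
sequence-only distances *predict* that overlap when no reference is
available. The target distance is computed from placements; the three
predictor distances are computed from the raw sequences alone, and
their predictive value is measured by percentile threshold rules.

## The four distances

**Overlap (target) distance `bt`.** For single placements,
bt = 1 − 2∇/(λ₁+λ₂), where ∇ is the size of the intersection of the two
placement intervals on the same reference (0 across references) and
λ₁, λ₂ are the read lengths. The 2/(λ₁+λ₂) scaling is the standard
length-symmetric overlap fraction: it is 0 for identical placements of
equal-length reads, 1 for disjoint placements, strictly decreasing in
∇, symmetric, and confined to [0, 1]. When a read maps more than once,
the mean over all placement combinations is used, in input order, so
the value is deterministic. Placement strand is ignored: two reads
covering the same interval from opposite strands do overlap on the
reference.

**Alignment-free distance `af`.** Tetramer (k = 4) relative frequencies
are counted with a sliding window; windows containing a non-ACGT
character are skipped *and excluded from the normalizing denominator*,
so the vector always sums to 1 over the valid windows (an all-ambiguous
read has no defined vector and is rejected). The distance is the
Euclidean norm of the difference of the two frequency vectors divided
by √2 — the exact maximum distance between two points of the
probability simplex (two disjoint one-hot vectors) — mapping onto
[0, 1]. k = 4 balances specificity of the words against the number of
cells (256) that a 40–300 bp read can populate; it is exposed as a
parameter but 4 is the default everywhere.

**Global-alignment distance `nw`.** The optimal global alignment score
S under +1 match / −1 mismatch / −1 gap (terminal gaps penalized like
any other). The distance is (Sₘₐₓ − S)/(Sₘₐₓ − Sₘᵢₙ) with the tight
per-pair bounds Sₘₐₓ = min(λ₁,λ₂) − |λ₁−λ₂| (all shorter-read bases
matched, unavoidable length-difference gaps) and Sₘᵢₙ = −(λ₁+λ₂)
(everything gapped; no alignment scores lower because a mismatch, −1
for two consumed bases, always beats two gaps, −2). The distance is 0
iff the score attains Sₘₐₓ, in particular for identical sequences. The
DP score itself is delegated to Biopython's `PairwiseAligner`; the test
suite checks it against an independent exhaustive enumeration.

**Local-alignment distance `bl`.** A self-contained stand-in for
pairwise `blastn` with word size 4 and masking/filtering off: if the
two reads share no exact 4-mer there is no seed and the score is 0
(distance 1); otherwise the optimal Smith–Waterman score under the same
+1/−1/−1 scheme is taken. Normalization is 1 − S/min(λ₁,λ₂), since
min(λ₁,λ₂) is the best achievable local score and the empty alignment
(score 0) the worst. E-values are not computed: for fixed read lengths
they are a monotone transform of the score and add nothing to a
percentile-based rule.

## Threshold predictors

α and β are nearest-rank percentile vectors of m = 100 levels:
component *i* is the value at rank ⌈i·n/m⌉ of the sorted sample. This
estimator is unambiguous under ties, exactly reproduces an equally
spaced sample, and is non-decreasing by construction.

Training evaluates, for every level αᵢ, all 100 candidate β values
(the predictor's percentiles) and adopts the one maximizing TPR + TNR
(Youden's criterion; ties go to the smallest β, i.e. the stricter
threshold, which favors precision at the small target values the
application cares about). The ≤ comparisons are applied literally; no
jittering of tied values.

Per-level ROC curves take one (FPR, TPR) point per candidate β plus the
(0,0) and (1,1) anchors, sorted lexicographically; AUC is the
trapezoidal area. Corner points of the empirical step curve are kept,
so with exhaustive thresholds the area equals the Mann–Whitney
statistic exactly, tied predictor values receiving the standard half
credit through diagonal segments. When the curve contains the ideal
point (0,1) the AUC is set to exactly 1.0 rather than summed, so the
perfect-predictor identity holds without float round-off. Levels at
which one class is empty (always the top level when half the pairs sit
at bt = 1, sometimes level 1 on small samples) get NaN β/AUC/rates and
are excluded from averages, with a logged count — never silently 0.

Cross-validation trains on one sample and evaluates on each of the
others, *pooling* the confusion counts of the test sets per level
before computing rates (the alternative — averaging per-set rates — is
nearly identical here but pooling weights every pair equally). Rates
are reported at the levels whose trained α is nearest the requested
reference values of the target distance; the default references are
0.105, 0.15, 0.205, 0.25.

## The synthetic-data generator

The generator emulates a short-read resequencing experiment reduced to
desk scale:

| parameter | default | meaning |
|-----------|---------|---------|
| `genome_length` | 50,000 bp | single uniform-random chromosome |
| `read_length_mean` ± `sd` | 100 ± 6 bp | rounded Normal, clipped to [4, genome length] |
| `n_reads` (rs) | 2,000 | forward reads; doubled to 4,000 by reverse complementation |
| `n_pairs` (rp) | 20,000 | pairs per subset |
| `n_subsets` | 6 | labelled A–F |
| `overlap_fraction` | 0.5 | exactly half of each subset overlaps |

Reads are exact substrings of the reference (no sequencing error — see
limitations). Each read gets a reverse-complemented copy with the same
placement on the '−' strand, so sequence-based distances face reads of
unknown orientation while the overlap truth is strand-agnostic, exactly
as for real aligned data. Read lengths are the simplest distribution
matching a mean ± sd summary; the defaults are the 100 ± 6 bp
Illumina-like regime, and 235 ± 4 or 75 ± 5 reproduce longer-/shorter-
read settings.

**Controlled pair selection.** The non-overlapping half is rejection-
sampled from disjoint-interval pairs. The overlapping half is drawn in
ten equal strata of target overlap degree (the intersection as a
fraction of the shorter read, 0–10 % … 90–100 %), each draw accepting
the available partner whose degree is nearest the stratum target; this
guarantees the whole bt range is populated so that all percentile
levels are informative. Overlapping pairs are drawn *strand-concordant*
(both members sequenced from the same strand). This is a deliberate
design choice: the tetramer vector of a reverse complement is a
permutation of the original's, so a strand-discordant overlapping pair
is statistically indistinguishable, to any of the sequence-based
distances as defined, from a non-overlapping pair — the target would be
unidentifiable from the data by construction. Every overlapping genomic
configuration remains represented, because each read's
reverse-complement twin is in the pool with the same placement. A
production prefilter would simply score both orientations of one read.

Subset seeds are spawned deterministically from the experiment seed;
pairs are unique within a subset, may recur across subsets (the shared
count is logged), and two runs with the same seed produce byte-identical
output files.

## What the synthetic results do and do not show

On the default conditions the AF predictor of bt reaches per-level AUC
≥ 0.99 at target percentiles 10–25 and cross-validated TP/TN rates
above 97 % at the four reference values, with Pearson correlation
corr(bt, af) ≈ 0.96 — the qualitative pattern (AF ≈ BL ≫ NW, precision
decreasing with level) expected for reads drawn error-free from a
non-repetitive random reference. Real genomes contain repeats (which
make distinct loci share tetramer profiles, inflating false positives)
and real reads contain errors and coverage biases; both degrade the
sequence-based distances but leave the target untouched. The synthetic
numbers are therefore an upper bound on real-data performance and a
correctness check of the machinery, not a claim about any particular
organism.

## Numerical and interface choices

- Coordinates are 0-based half-open throughout; SAM's 1-based POS is
  converted on ingestion, the end coordinate comes from the
  reference-consuming CIGAR length, and reverse-strand SEQ fields are
  reverse complemented back so `Read.seq` is always the as-sequenced
  orientation. Unmapped records are dropped with a logged count.
- `af` is clamped at 1.0 against a one-ulp overshoot of the √2
  division; all distances otherwise carry full double precision, and
  pair TSVs serialize floats at 17 significant digits with
  round-trip-exact parsing ("NA" for missing).
- Problem sizes: the default experiment (6 × 20,000 pairs over 4,000
  reads) runs in ~20 s on one CPU including training and
  cross-validation; `af` over a sample is a vectorized matrix operation
  over precomputed 256-dim vectors, and alignment distances cost a few
  tens of microseconds per 100 bp pair.
- Degenerate inputs fail loudly: empty reads for aligners, all-N reads
  for `af` (flagged per pair in batch mode, the run continues),
  degenerate (constant) targets for training, zero-variance columns for
  correlations.

## Known limitations

- No sequencing-error model; an optional uniform substitution mode was
  considered and left out to keep the generator a faithful rendition of
  the error-free design it mirrors.
- The local aligner seeds on exact shared words of length 4 and then
  scores the full Smith–Waterman optimum; unlike BLAST it performs no
  X-drop truncation or HSP statistics, so it is an idealized (slightly
  generous) version of the heuristic.
- Single-chromosome simulation only; multi-reference pairs would be
  trivially disjoint and add nothing to the threshold analysis.
- BAM/CRAM, paired-end mates and quality-aware processing are out of
  scope; SAM, FASTA/FASTQ and TSV are the exchange formats.
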