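# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `gridmsa`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Alignment model

All dynamic programming uses the three-state affine-gap formulation: for a
cell (i, j),

    E(i,j) = max( H(i,j−1) − open_b(j−1),  E(i,j−1) − ext_b(j−1) )   # gap in a
    F(i,j) = max( H(i−1,j) − open_a(i−1),  F(i−1,j) − ext_a(i−1) )   # gap in b
    H(i,j) = max( H(i−1,j−1) + s(i,j),  E(i,j),  F(i,j) )

maximized over scores, with H additionally floored at 0 in local
(Smith–Waterman) mode.  Pairwise stage-1 alignments run in local mode with
constant gap costs; stage-3 profile merges run in global mode with
position-specific costs read from the profile gap rows (indexed by the
consumed column, so a gap opened against column c pays that column's
penalty).

**Integer scale.**  Scores and penalties are multiplied by 100 and rounded to
integers once, at scheme/profile construction; all DP arithmetic is exact
64-bit integer, and cells must fit signed 32 bits (overflow raises, never
wraps).  Unreachable gap states carry the sentinel `NEG_INF = −2^30`, which is
absorbing under the clamped recurrences and can never win a max against a
reachable value at supported problem sizes.

**Determinism.**  Tie-breaks are fixed everywhere: in traceback, diagonal >
vertical (gap in b) > horizontal (gap in a), and within a gap state closing
the gap beats extending it; among equal-scoring local maxima the smallest
(i, then j) wins; NJ Q-ties resolve to the smallest (i, j); midpoint-path ties
resolve to lexicographically smallest leaf names.  prfscore cells are computed
in a fixed-order summation kernel rather than BLAS, because BLAS reassociates
sums depending on operand shape and stride, which would let the ×100 rounding
flip with the block partition.  Consequently every user-visible output is
bit-identical across worker counts, block counts k, and fragment policies.

## Blocked engine and grid cache

The DP matrix is cut into k × k blocks per `axis_bounds` (segment sizes
differ by at most one, larger segments first).  k is the per-axis block
*count*; k = 1 is plain full-matrix DP.  The forward pass fills blocks along
anti-diagonals (wave-front order) and keeps only boundary rows/columns of
(H, E, F) — exactly (k+1)(len_a+len_b+2) cells.  Traceback is a separate job:
it walks from the end cell (global corner, or recorded local maximum) to the
origin, re-deriving each visited block's interior from its cached boundary,
so it never reads an interior cell it has not itself recomputed.

Caches serialize to a little-endian byte stream (magic, codec, mode, k,
lengths, best cell, then boundary rows and columns cell-major).  Two cell
codecs exist:

- **absolute, 12 bytes**: three int32 values (h, e, f) — the default;
- **relative, 6 bytes**: int32 h plus int8 offsets e−h and f−h, valid only
  while both offsets are < 128 in magnitude; the int8 value −128 is reserved
  to encode the `NEG_INF` sentinel.  Under score maximization, |h−e| grows
  past 128 for any realistic scheme (each match adds ~100 units while E
  decays by the extend cost), so serializing a typical cache with this codec
  raises the documented overflow error directing users to the absolute codec.
  It remains available for cost-like schemes with sub-1.28-point penalties.

**k selection.**  Optimal k is hardware-dependent, so the engine exposes the
mechanism rather than constants: a user-supplied calibration table of
(length, k) points is interpolated piecewise-linearly on max(len_a, len_b)
and rounded; without a table the portable default `ceil(sqrt(max_len/64))`
clamped to [1, 16] is used.  Either way k is clamped to [1, min(len_a,
len_b)].  Results never depend on k; only memory/recomputation trade-offs do.

## Scheduler

Workers are an OS thread pool; *geometries* are named rectangular capacity
sub-pools with a designated controller (capacity + mutual exclusivity, not
pinned hardware).  Stage 1 distributes its n(n−1)/2 independent jobs
round-robin across forward geometries, each forward job serializing its grid
cache to bytes that a backward geometry deserializes for traceback (a failing
job is retried once).  Stage 3 has only one alignment in flight at a time, so
it spreads each merge's blocks across the pool along anti-diagonals.  The
default 60-worker pool yields four 7×2 forward plus two 2×1 backward
geometries (56:4, reflecting the forward pass's dominant cost); batches of
5–8 jobs instead get eight 7×1 forward geometries, with backward jobs reusing
freed forward geometries.  Smaller pools scale the pattern down: up to two
2×1 backward geometries when the pool affords them, the remainder split into
at most four equal forward geometries.  Four management workers are modeled
as `reserved` metadata and never scheduled.

## Profiles

A profile is 35 × m: rows 0–32 are residue categories (16 IUPAC nucleotide
codes or 23 amino-acid codes, padded with zero rows to 33), row 33 the
position-specific gap-open penalty, row 34 gap-extend.  Residue rows hold the
substitution matrix applied to the weighted residue frequencies of the column
(averaged over total member weight, so an all-gap column is all zero);
prfscore(p1, p2, i, j) is the dot product of p1's residue rows at column i
with p2's frequencies at column j, equal to `f₁ᵀ M f₂` and hence symmetric
for symmetric M.  Gap rows are excluded from the product.  The 33 + 2 split
and the row contents are this package's interpretation of the fixed 35-row
layout; alternatives (e.g. counting the gap symbol among the categories)
would be behaviorally equivalent given the scoring above.

Position-specific penalties are the scheme's base values scaled by
`1 − 0.7 · gap_fraction` of the column, which concentrates new gaps where
gaps already exist.  Residue-usage-specific rules (e.g. hydrophilicity runs)
are deliberately out of scope; this scaling hook is where they would attach.
With the fragment-transfer policy on, each block job copies just the profile
fragments it needs before scoring — a data-movement policy only, verified to
change nothing.

## Defaults and parameters

| Parameter | Default | Notes |
|---|---|---|
| DNA substitution | match +1, mismatch 0 | exact-match identity over IUPAC codes; ambiguity codes score as mismatches |
| DNA gaps | open 15, extend 6.66 | Clustal W 1.83 defaults |
| Protein substitution | BLOSUM62 | via biopython; B/Z/X included, U→C, O→K at encoding |
| Protein gaps | open 10, extend 0.1 | Clustal W 1.83 defaults |
| Distance | 1 − fractional identity | over residue–residue columns of the local alignment; empty alignment → 1.0 |
| Kimura correction | off | `−ln(1 − d − 0.2 d²)`, capped at 10 beyond d = 0.75 |
| k | auto | `ceil(sqrt(max_len/64))`, clamped [1, 16] |
| Cell codec | absolute (12 B) | relative (6 B) available |
| Pool / reserved | 60 / 4 | geometry layout as above |
| Alphabet detection | ≥ 85% of residues in {A,C,G,T,U,N} → DNA | |

Negative NJ branch lengths are clamped to zero with the deficit moved to the
sister branch.  Leaf weights are floored at 1e−8 after normalization so a
zero-length leaf still contributes; an all-zero-length tree gives equal
weights of 1.

## Synthetic data

`random_family` emulates a sequence family: one uniform-random ancestor and n
descendants mutated independently — per-site substitutions with probability
`sub_rate` (replacement uniform over the other residues), per-site indel
events with probability `indel_rate`, insertion/deletion equally likely,
lengths geometric with mean `indel_mean`.  Defaults (n = 10, length 2000,
sub 0.05, indel 0.01, mean 3) are the package's desk-scale standing
conditions: ten related kb-scale sequences, divergent enough that alignments
contain real gaps but the family remains recoverable.  The generator is a
star phylogeny — no rate heterogeneity, no sequence composition bias, no
rearrangements or duplications — so passing tests demonstrate algorithmic
correctness and determinism, not biological accuracy on real genomes; the
aligner itself makes no star-tree assumption.  Test and acceptance runs use
families of 10 × ~2 kb (and smaller), a deliberate scale-down of kb-range
benchmark conditions chosen so the whole suite runs in minutes on one CPU;
the algorithms are identical at any length.

## Implementation notes

- DP kernels and the prfscore block kernel are numba-jitted (nogil), which is
  what makes kb-scale runs practical; forward block interiors are transient —
  only the grid cache persists between the forward and backward halves.
- Engine correctness is checked against an independently written full-matrix
  Gotoh aligner with stored traceback pointers (`tests/oracle.py`), and merge
  scores against independent column-wise affine rescoring of the move path;
  NJ topology is cross-checked against scikit-bio on additive matrices.
- File formats: FASTA (wrapped, 60 cols), CLUSTAL (60-residue interleaved
  blocks, ids truncated to 30 chars), Newick (5-decimal branch lengths,
  trifurcating root for unrooted NJ trees), PHYLIP square matrix (ids padded
  to 10 chars — longer ids are truncated in this file only — distances to 6
  decimals).

## Known limitations

- No iterative refinement and no anchoring heuristics: cost is quadratic per
  merge, which is the intended trade-off (exact DP for few, long sequences).
- Guide-tree quality degrades for very divergent families (> ~75% distance)
  where uncorrected identity distances saturate.
- Position-specific gap penalties implement only gap-fraction dilution, not
  residue-composition rules.
- Thread-based workers share one interpreter; speedups come from the nogil
  kernels and matter less than the determinism contract, which is the point
  of the scheduler model.
- `SequenceSet` requires all sequences to share one alphabet; mixed
  DNA/protein inputs are rejected rather than translated.
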