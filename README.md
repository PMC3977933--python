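# gridmsa

Progressive multiple sequence alignment of DNA or protein sequences, built
around a blocked dynamic-programming engine with a *grid cache*.

`gridmsa` is for researchers who need full dynamic-programming alignments of a
modest number (2–~100) of relatively long sequences — viral genomes, organelle
genomes, long amplicons — where k-mer/anchoring heuristics lose accuracy in
highly polymorphic regions and GPU aligners run out of memory.  It follows the
classic Clustal W three-stage strategy while restructuring every DP fill so
that the expensive forward pass and the cheap traceback are decoupled,
schedulable jobs.

## The method

**Stage 1 — distances.**  Every pair (i, j) of the n input sequences is
aligned locally under the Smith–Waterman/Gotoh affine-gap model
(H/E/F recurrences, gap cost `open + k·extend`), giving n(n−1)/2 independent
jobs.  Each alignment becomes a distance
`d(i,j) = 1 − identities / residue–residue columns`, filling a symmetric
matrix with zero diagonal (an optional Kimura multiple-hit correction is off
by default).

**Stage 2 — guide tree.**  Saitou–Nei neighbor joining on the distance matrix
(iteratively join the pair minimizing `Q(i,j) = (r−2)d(i,j) − R_i − R_j`)
yields an unrooted tree with branch lengths; it is midpoint-rooted, and each
sequence receives a branch-sharing weight: the sum over its root-to-leaf path
of `branch length / leaves below that branch`, normalized to a maximum of 1.

**Stage 3 — progressive alignment.**  Groups are merged bottom-up along the
rooted tree.  Each group is summarized as a 35 × m *profile* — 33 residue
category rows holding the weight-averaged substitution-matrix column of the
residues observed, plus position-specific gap-open and gap-extend rows.  The
profile–profile cell score (*prfscore*) is a plain vector product
`f₁ᵀ M f₂` of one column from each profile, and each merge is one
quadratic-space global DP on the same engine, with gap penalties read from the
profile gap rows.

**The engine.**  Every DP fill is partitioned into a k × k grid of blocks
filled in wave-front order (block (i,j) waits only on (i−1,j) and (i,j−1)).
Only block-boundary (H, E, F) cells are kept — the grid cache, at most
`(k+1)(len_a+len_b+2)` cells — and the traceback job recomputes block
interiors on demand from those boundaries.  Caches serialize to a byte stream
with a 12-byte absolute cell codec (or a 6-byte relative codec when
|h−e|, |h−f| < 128), which is exactly how forward and backward jobs hand off.
A scheduler models a fixed worker pool partitioned into rectangular forward
and backward *geometries* (on a 60-worker pool: four 7×2 forward plus two 2×1
backward geometries; eight 7×1 forward geometries for batches of 5–8 jobs).
All arithmetic is integer (scores × 100), every tie-break is fixed, and all
outputs are bit-identical for any worker count, any k, and either
profile-fragment transfer policy.

## Worked example

```sh
$ gridmsa generate -n 5 --length 400 --seed 42 -o family.fasta
wrote 5 sequences (~400 bp, seed 42) -> family.fasta

$ gridmsa align family.fasta -o family.aln --fmt clustal \
    --tree-out family.nwk --dist-out family.phylip
aligned 5 sequences into 410 columns -> family.aln
```

`generate` simulates a family: one random 400-bp ancestor and five
descendants with 5% per-site substitutions and 1% indels.  `align` runs the
three stages and reports that the five sequences fit in 410 alignment
columns (the extra 10 columns absorb the indels).  The distance matrix
(`family.phylip`, PHYLIP square format) holds the stage-1 identities:

```
    5
seq1       0.000000 0.213568 0.203518 0.265464 0.206633
seq2       0.213568 0.000000 0.097990 0.175258 0.106599
...
```

e.g. seq2 and seq3 are the closest pair (9.8% of aligned residue pairs
differ), so they are joined first.  The guide tree (`family.nwk`) confirms:

```
((seq1:0.13115,(seq2:0.02310,seq3:0.07489):0.02839):0.02112,seq4:0.13427,seq5:0.03327);
```

and the alignment itself (`family.aln`, CLUSTAL format, 60-residue blocks):

```
seq1      ATGCATAGAAGTGTGTGATCGCATTGTTGCCAAGTATGATGCATCTG--TTACCCAGAGG
seq2      ATGCCTAGAAGTGTGTGTTCGCATTGCTGCCAAGTATTCGAAGCATCTGTTACCCAGAGG
seq3      AGGCCTAGAAGTGTGTGATCGCATTGCTGCCAAGTATTCGATGCATC--TTACCAAGAGG
...
```

Gap-stripping any row reproduces the corresponding input sequence exactly.
The same pipeline is available as a library:

```python
import gridmsa as g

fam = g.random_family(n=10, length=2000, seed=0)
result = g.align_sequences(fam)
result.msa        # the alignment
result.nj_tree    # unrooted NJ guide tree
result.distances  # stage-1 distance matrix
```

Other subcommands: `gridmsa distances` (stage 1 only), `gridmsa tree`
(NJ from a PHYLIP matrix).  Useful flags: `--gapopen/--gapext`, `--type`,
`--matrix` (NCBI/EMBOSS plain-text substitution matrix), `--k`, `--workers`.

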