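# Methods

## Problem setting

Given a foreground set of DNA sequences believed to share a
transcription-factor binding motif and a background set modelling chance
occurrence, the package searches for consensus patterns whose occurrence
count in the foreground exceeds its length-scaled background expectation.
The search space is seeded with two-triplet gapped consensuses
`UVW·N^g·XYZ` (g = 0..14), which lets the same procedure find both
contiguous and gapped motifs (e.g. the Gal4-type `CGG·N11·CCG` dyad) up
to 20 nt.

## Enrichment model

For a pattern with foreground count C and background count N, the
expectation is `E = N·L_fg/L_bg`, with L the total nucleotide lengths
(N residues included; no masking is applied). Fold enrichment is
`F = C/E` and significance is the binomial z-approximation

    Z = (C − E) / sqrt(E·(1 − p)),   p = L_fg / L_bg,

which is exact for the model in which each of the N background instances
falls into the foreground independently with probability p. Two
consequences matter in practice:

- When `E = 0` we define F = ∞ for C > 0 (the pattern trivially passes
  any fold filter), F = 1 for C = 0, and Z = 0 — a pattern absent from
  the background carries no calibrated significance, only a fold flag.
- The variance vanishes as p → 1, so the background must be larger than
  the foreground for Z to rank anything. The synthetic generator
  therefore defaults to a background 4× the foreground, mirroring the
  real use case where the background (all promoters, a whole array) is
  much larger than any target set.

Counting is strand-symmetric: patterns are matched on both strands, all
overlapping occurrences count, and counts are pooled across sequences
(a per-site statistic, not per-sequence). A self-reverse-complementary
pattern is scanned forward-only so palindromic sites are never counted
twice. Sequence letters outside ACGT are folded to N on input and an N
never satisfies a specified pattern position, so ambiguous input cannot
inflate counts.

## Stage parameters

| stage | parameter | default | meaning |
|---|---|---|---|
| filtering | `min_fold` | 1.2 | minimum F for a core to survive |
| filtering | `top_k_cores` | 50 | cores retained, ranked by Z |
| filtering | `max_gap` | 14 | largest N-run between triplets |
| degeneration | `max_changed` | 4 | informative positions relaxed |
| extension | `max_changed` | 3 | N positions specialized per round |
| extension | `large_fg_threshold` | 100,000 nt | second round trigger |
| refinement | `scan_mismatch` | 1 | mismatch allowance when scanning |
| refinement | `markov_order` | 3 | background model order |
| redundancy | `cutoff` | 0.6 | similarity above which motifs merge |

All ranking ties are broken lexicographically on the pattern string, so
every stage is fully deterministic.

## Fast exact counting

The stages are exhaustive searches made cheap by counting from
sufficient statistics instead of rescanning, using the identity
`count(V) = fwd(V) + fwd(revcomp(V))` (second term dropped when V is
self-reverse-complementary), where `fwd` counts forward-strand text
matches:

- *Core filtering and degeneration* use per-gap 64×64 triplet-pair count
  matrices (`M_g[k1,k2]` = occurrences of triplet k1 followed gap-g-later
  by triplet k2). Any core count is two matrix entries; any degenerate
  consensus count is a block sum, evaluated for all 8⁶ code combinations
  at once by tensor contraction with per-position code-indicator
  matrices.
- *Extension* exploits the fact that every occurrence of a specialized
  variant is an occurrence of its parent consensus: the parent's match
  sites are collected once and joint base histograms at the positions
  being specialized yield all candidate counts. Self-complementarity of
  candidates is detected combinatorially per position combination.

Both fast paths are cross-checked against the naive scanner in the test
suite. The extension search is exact up to 5×10⁶ candidates (the default
geometry peaks at ≈1.25×10⁶); beyond that a greedy best-single-change
loop is used.

## MAP refinement

Instances of the extended consensus (flanking all-N columns trimmed
first — they carry no information and would dilute the width term) are
scanned with one mismatch and scored with the modified MAP objective

    MAP = ln(w) · (ln x_m / w) · [ Σ_ij p_ij ln p_ij − (1/x_m) Σ_s ln p0(s) ],

natural logarithms throughout. `p_ij` are the raw per-position
frequencies of the x_m instance sites (no pseudocount, so that x_m
identical sites on a uniform background give exactly
`ln w · ln x_m · ln 4`, a closed form the tests pin to 1e-9). `p0(s)` is
the probability of site s under an order-3 Markov model fitted to the
background on both strands with pseudocount 1 per cell; each base is
conditioned on the three preceding bases taken from the instance's own
strand, backing off to lower orders near sequence starts. Instances
whose site or left context contains an N are excluded (they cannot be
scored).

Pruning is a single leave-one-out pass: instance i is preserved iff
MAP(all) > MAP(all − i), every test against the full set, no iteration —
the result is order-independent. A lone instance is preserved; if
nothing survives, all scanned instances are kept (logged). The
*reported* PWM adds a 0.25 pseudocount per cell to avoid zero columns
downstream; the objective itself never uses it.

## PWM similarity and evaluation

CompareACE-style similarity: Pearson correlation between the aligned
4×overlap probability blocks, maximized over all ungapped offsets with
at least 6 overlapping columns and both orientations. Zero-variance
blocks score 0 rather than leaving the correlation undefined; among
equal-scoring alignments (periodic motifs) the fullest, most central,
same-strand alignment is reported. Redundancy removal greedily keeps
the highest-MAP representative of each similarity class.

Evaluation aligns expected and identified PWMs the same way and counts
alignment columns: TP (shared), FP (identified only), FN (expected
only); then `mSN = m·TP/(TP+FN)` and `mSP = m·TP/(TP+FP)` with negative
m clamped to 0. The success rate takes, per benchmark case, the best
similarity among the tool's top three motifs and thresholds it.

## Synthetic data

The generator emulates the discovery setting: background sequences from
an order-0 uniform model (or any fitted Markov background), foreground
from the same model with one motif instance planted in a chosen fraction
of sequences at a uniform position and strand (ZOOPS-like; multiple
instances per sequence available behind a flag). IUPAC positions are
sampled uniformly from their allowed bases; optional per-position
mismatches are injected at a stated rate; every planted site is recorded
as ground truth, and identical specs and seeds give byte-identical
FASTA. Default conditions: 200 foreground sequences × 500 bp, 40%
planted, background 4× the foreground, mismatch rate 0.

What it does not emulate: read-level ChIP noise, peak-shape positional
bias, GC/nucleosome composition, repeats, or co-occurring motifs.
Passing recovery tests on this generator demonstrates the machinery is
correct under its stated model, not performance on real chromatin data.

## Problem sizes used in tests

Unit tests run on small randomized fixtures (tens of sequences, 100-300
bp). The end-to-end recovery benchmarks use 200×500 bp foregrounds with
an 800×500 bp background; one full default-parameter run completes in
roughly 10-15 s. The acceptance script uses a 60×300 bp foreground
(background 4×) with an 80% plant, which drives hundreds of cores past
the fold filter while keeping the whole-space stage fast.

## Known limitations and design notes

- The z-score presumes the foreground is small relative to the
  background; with equal sizes every deviation becomes infinitely
  significant and ranking degenerates (the generator's 4× default avoids
  this).
- Extension selects the max-Z variant among ~10⁶ candidates; on data
  with no true flanking signal, broad-code variants that thin the
  background counts slightly more than the foreground by chance can
  still edge out the unextended form by 1-2 z-units. This is inherent to
  exhaustive max-statistic selection; the unextended form is returned
  only when no variant strictly beats it.
- Per-sequence (ZOOPS/OOPS) counting models, EM/Gibbs refinement, motif
  clustering/averaging, and width re-optimization during refinement are
  out of scope; width is fixed by the extended consensus.
- Degeneration relaxes exactly the six core slots to consistent codes
  (7 non-identity options each, ≤4 changes: 43,653 candidates per core).
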