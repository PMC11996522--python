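# Methods

## Data model

Gene coordinates are 1-based inclusive base pairs (the GFF3
convention); gene order on a chromosome is defined by start coordinate
and indexed from 0. Strand is stored but never affects order, because
dot plots are built from gene order alone. Genes without an orthogroup
assignment keep their order indices but generate no homology dots.

A tandem duplication equivalence class (TDEC) is a maximal run of
consecutive genes on one chromosome all in the same orthogroup,
represented by its first member. Condensation is idempotent, and all
synteny is computed between TDECs; TDEC expansion back to genes is
implemented but off by default. Inter-copy genomic distances are
measured between TDEC span edges (gap between the nearest ends of the
two copies' bp spans); copies on different chromosomes have infinite
distance. The anchor convention for distances is a package choice —
only the binning of distances depends on it.

## Nanosynteny and its nulls

Nanosynteny blocks are maximal runs of dots with step (+1, +1)
(diagonal) or (+1, −1) (antidiagonal). Inversions preserve gene order
read in reverse, so antidiagonal runs count as nanosynteny; a
configuration flag restricts to diagonal-only. A dot may sit in one
diagonal and one antidiagonal run simultaneously; both are reported.
In run censuses, length-1 antidiagonal runs are suppressed so isolated
dots are counted once; the diagonal/antidiagonal conventions agree for
every k ≥ 2, the only regime used. Retained blocks need k ≥ k_min
pairs and ≥ 3 distinct orthogroups (runs with fewer distinct
orthogroups are complex tandem-duplication artifacts).

Two nulls quantify how many blocks of each size arise by chance:

* **Permutation null.** Each of `n_swaps` steps (default 30,000) picks
  two random rows and two random columns and exchanges them; this
  preserves row and column sums exactly. The permutation is composed
  as an index map and applied to the sparse dot set, so the cost is
  O(n_swaps + n_dots). f̂_k is the randomized block count of size k
  over the observed count.
* **Analytic null.** Dots are modeled as independent Bernoulli(q) with
  q = n_dots/(n_a·n_b). On a line of L cells the expected number of
  maximal runs of length exactly k is q^k for k = L and
  2·q^k(1−q) + (L−k−1)·q^k(1−q)² for k < L (end and interior
  placements). Summing over the diagonal-length multiset of an
  n_a×n_b matrix, for both orientations, gives the expected run count.
  At q = 1 the formula collapses to the deterministic run census of
  the full matrix, and it matches permutation Monte-Carlo within
  sampling error at the sparsities tested (the exact row/column-sum
  conditioning of the permutation null is an O(1/n) effect there).

`choose_k_min` returns the smallest k whose chance fraction is below a
significance level (default 0.05) in every supplied comparison. The
permutation estimate is the ground truth; the analytic form is a fast
screen.

## Microsynteny assembly

Distances in dot-plot coordinates are Chebyshev (max of the two axis
gaps), so `d_dot_max = 1` coincides with diagonal adjacency. Anchor
pairs within `d_nano_max` (endpoint-to-endpoint, minimized over the
four endpoint combinations) are candidate merges, processed in
ascending distance order; a merge requires a bridging path of dots
with consecutive Chebyshev steps ≤ `d_dot_max`. The path search is a
breadth-first search from each anchor endpoint with lexicographic
tie-breaking, so outputs are deterministic; among fewest-hop paths the
lexicographically smallest is kept. Because merging is a union over
connected components, the final partition is independent of processing
order. A micro block's pair list is the union of its member anchors'
pairs and all bridging dots, sorted; every micro block contains at
least one anchor by construction. Bridging paths may pass through dots
of other anchors unless `exclusive_paths` is set.

Defaults: `k_min = 3` (the chance-fraction analysis), `d_dot_max = 3`
(genome coverage plateaus there when gaps are small), `d_nano_max = 5`
(coverage is insensitive to it; documented, configurable).

## Duplication detection and source assignment

Self-comparison micro blocks pass three filters: (1) blocks aligning a
chromosome's genes with themselves (the trivial diagonal) are dropped;
(2) blocks containing any TDEC twice are dropped; (3) overlapping
blocks on one chromosome pair — overlap being the smaller of the
shared-TDEC counts on the two axes — are resolved by keeping the block
with more pairs, ties broken toward the earlier (chromosome, start)
position via a greedy largest-first sweep, which makes the filter
idempotent. Each surviving off-diagonal block with ≥ 3 distinct
orthogroups is one duplication event; its mirror image (axes swapped)
is deduplicated, and copy1 is the copy earlier in (chromosome, span)
order. No duplication mechanism (segmental, WGD remnant, complex
tandem) is inferred.

The source copy is the copy whose genes sit in the larger
cross-species microsynteny block against the reference (primary
microsynteny = ancestral flanking context). Equal block sizes or
missing cross-species synteny leave the event undetermined and exclude
it from polarity statistics. Triplets pair the source member, target
member and the reference partner of the source member inside the
source copy's largest cross-species block, one per orthogroup present
in all three regions.

## Divergence and rates

Divergence is the Levenshtein edit distance (computed with the
bit-parallel edlib library), normalised per site by the longer
sequence length — symmetric and bounded by 1; mean-length
normalisation is available. Amino-acid distances avoid the saturation
of non-synonymous nucleotide substitutions at deep divergences.
ΔdL = d_L(A1,B1) − d_L(A2,B1); exact zeros are tracked as their own
category and excluded from conditional probabilities. Substitution
rates divide both distances by the same duplication time, so every
sign-based statistic is invariant to the denominator convention; no
branch-specific rate model is attempted.

## Duplication dating

Gene-tree duplications are found by species-overlap (LCA) mapping: an
internal node whose children's species sets intersect is a
duplication, mapped to the species-tree MRCA of its leaf species. This
replaces full duplication–loss–coalescence reconciliation; the module
also accepts precomputed (pair, node, support) tables so an external
reconciler's output can be plugged in. Support is the fraction of
species below the mapped node that retain both paralogs; a species
counts as retaining only if both copies are present. For a multi-gene
duplication the oldest node with support ≥ 0.5 wins, falling back to
the oldest node overall.

The second estimate scans every genome for ≥ 2 disjoint
order-preserving occurrences of the duplicated orthogroup sequence
(both orientations, index gaps up to `max_gap`, default 3, mirroring
the microsynteny tolerance; exact-contiguous mode available) and takes
the species-tree MRCA of all multiple-copy species.

The consensus node is the older of the two (an upper-bound
preference), and t_dup is the midpoint of the consensus node's age and
its parent's age; a root-mapped duplication has no parent and uses the
root age itself, again a lower bound on the midpoint. Classification
against a reference is after-speciation iff t_dup is strictly less
than the pairwise divergence time; equality counts as
before-speciation. All three choices bias toward *over*estimating
duplication ages, which keeps the after-speciation triplet set — the
only set where ΔdL isolates rate differences from divergence-time
differences — conservative. Note that LCA mapping itself dates a
duplication at the crown of the clade that inherited it, a lower bound
on the true event time; the midpoint rule deliberately pushes the
estimate back into the branch above.

## Polarity statistics

P(ΔdL<0 | ΔdL≠0) is reported pooled, per duplication-age bin (default
10 MY bins, plus a cumulative curve and the Spearman correlation of
sign(ΔdL) with age), and binned by target-copy size and inter-copy
distance (default log-spaced bp edges up to 1 Mb plus an infinite bin
pooling interchromosomal events). Per-bin sign fractions sum to 1.

The block-wise polarization test asks whether polarity is decided per
duplication rather than per gene: the statistic is the fraction of
multi-triplet duplications whose within-block P_SB(ΔdL<0) is exactly
0 or 1, and the null resorts triplet signs across duplications while
preserving the block-size multiset (sign permutation; whole-triplet
resorting is equivalent for this statistic). Single-triplet blocks are
excluded as trivially extreme. p = (1 + #{T_null ≥ T_obs})/(1 + N).
The p-values are valid but conservative for coarse block structures
(the statistic is discrete); calibration checks use many
variable-sized blocks.

Bootstrap robustness draws species subsets without replacement and
recomputes the pooled probability from triplets whose focal *and*
reference species are both drawn.

## The synthetic generator

The generator is the package's ground-truth test surface. An ancestral
genome (default 2 chromosomes × 100 genes, each gene founding its own
orthogroup) descends a calibrated species tree (supplied newick or a
random coalescent-style topology with sorted uniform node ages;
default crown age 100 MYA). Along each branch, sequences evolve by
per-site uniform replacement — substitution probability 1 − exp(−rt) —
and Poisson-distributed inversions, translocations and deletions
rearrange gene order. Planted duplications copy a contiguous segment
at a specified time on a specified root-to-leaf path; the original
segment is tagged source, the inserted copy target, and each copy
evolves at its own rate thereafter. A ledger records every planted
event (gene ids per species, time, rates, chromosomes) and true gene
trees are emitted directly from the known history, so dating tests are
not confounded by tree-estimation error.

Defaults are chosen once as mammal-like study conditions: base rate
1e-3 substitutions/site/MY (≈ 0.2 substitutions/site across an 87 MY
divergence, the scale of a human–mouse comparison), 300-residue
proteins, genes every 2 kb. Optional processes: tandem arrays
(consecutive same-orthogroup copies), dispersed single-gene duplicates
(which create the off-diagonal background dots real gene families
produce), and an indel mode (without it Levenshtein reduces to Hamming
on equal-length pairs, isolating the rate-asymmetry signal from
alignment-length effects).

What the generator does **not** emulate: empirical amino-acid exchange
matrices or site-rate heterogeneity, gene conversion between
paralogs, whole-genome duplication, assembly or annotation error, and
orthogroup mis-clustering (orthogroups are known exactly). Passing
tests therefore demonstrate algorithmic correctness under the stated
model, not robustness to those real-data pathologies. Constraints kept
for ledger fidelity: each orthogroup carries at most one planted
duplication, rearrangement breakpoints avoid planted-copy genes, and
deletions spare them; true gene trees are emitted only for single-copy
and once-duplicated orthogroups (tandem-array orthogroups are
skipped).

## Numerical and edge-case choices

* All stochastic operations take explicit seeds and are bit-reproducible.
* Ties in primary-microsynteny size → earliest (chromosome, start)
  block; ties in source assignment → undetermined (excluded); ties in
  filter-3 block size → the later block is removed.
* Statistics conditioned on ΔdL ≠ 0 return None (undefined) when no
  nonzero triplet exists; empty bins report n = 0 with NaN fractions;
  bootstrap samples with no retained nonzero triplet are skipped with
  a warning.
* `consensus_time` on a root-mapped node returns the root age.
* The analytic null's k = 1 count includes isolated dots once per
  orientation, unlike the census convention; k = 1 is never used.

## Problem sizes in tests and the acceptance script

Test batteries use genomes of 25–80 genes per chromosome and 2–6
species; oracle-equivalence checks run 500+ random matrices up to
15×15; the null-model comparison uses 200×200 matrices at
q ∈ {0.005, 0.01, 0.02} with 30,000-swap randomizations; calibration
batteries use 1,000 triplets of 300-residue proteins. These sizes were
chosen so the full suite and the acceptance script each complete in
well under a minute while leaving Monte-Carlo standard errors small
relative to the tested tolerances.

## Known limitations

* The Bernoulli analytic null ignores row/column-sum conditioning;
  it is validated against the permutation null only at the sparsities
  above.
* The greedy disjoint occurrence scan in the multiple-copy MRCA search
  is not an exhaustive maximum-matching; with heavily overlapping
  repeats it can undercount copies (and thus under-age an event,
  which the consensus max rule mitigates).
* f/f\* use TDEC representatives' sequences; member-level variation
  within a tandem array is not examined.
* LCA mapping under-dates duplications whose descendant copies were
  lost in basal lineages; the multiple-copy MRCA method and the
  midpoint rule partially compensate, but dating remains a lower-bound
  construction on sparse clades.
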