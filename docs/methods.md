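# Methods

## Model

A sequence is a word *x* of length *n* over a finite ordered alphabet Σ of
size σ; letters are rank-mapped to integers 0..σ−1 in their natural sort
order, so the machinery is alphabet-agnostic (DNA, protein, or integer
tokens for σ > 26). Occurrences overlap: f(TT) = 2 in TTT.

The expected frequency E(w) = f(w_p)·f(w_s)/f(w_i) treats an occurrence of
the maximal infix w_i as extendable to w_p on the left with probability
f(w_p)/f(w_i) and to w_s on the right with probability f(w_s)/f(w_i), and
multiplies the product by f(w_i). The two extension events are not
independent in general; no correction is applied — the estimator is used
verbatim, as is standard for this composition-based null. The deviation
dev(w) = (f(w) − E(w))/max(√E(w), 1) clamps the χ² denominator at 1 so
that rare words (E < 1) are scored by their absolute deficit rather than
inflated by a tiny standard error. ρ < 0 is a user threshold, not a
significance level; with a ρ near 0 the deviation-sorted output doubles as
a ranking from which the extreme words are read off.

Boundary conventions: dev(w) = ρ counts as avoided; k ≤ 2 and ρ ≥ 0 are
input errors; k > n+1 returns an empty result rather than an error (no
word that long occurs, and no minimal absent word exceeds n+1). The
threshold comparison always uses the unrounded float deviation; the
6-decimal figures in reports are formatting only, and each record carries
the exact integer triple (f_p, f_s, f_i) so E is reproducible as a
rational.

## Data structures

The suffix tree is built over x·$ (one unique sentinel per sequence) with
Ukkonen's online algorithm in flat arrays; children live in per-node dicts
keyed by first-edge-letter rank. A single depth-first pass (children in
letter-rank order, so all outputs are deterministic) annotates word-depth
D(v), subtree terminal count C(v), parent links and the smallest terminal
index below each node. The sentinel-only leaf is excluded from C, so C(v)
equals the observed frequency of the sentinel-free path label, and leaf
depths exclude the trailing sentinel. Arbitrary factors are located by
O(k) descent; the count at an implicit position on edge (u, v) is C(v).
The O(1) weighted-ancestor locus retrieval for MAW prefixes was not
implemented — descent changes constants, not results.

Minimal absent words: writing a MAW as a·u·b, some occurrence of u is
followed by b and the a-preceded occurrence is not, so u is right-branching
in x·$ and hence an explicit node. One postorder pass merges, bottom-up,
each node's set of left-extension letters (a bitmask, so any σ ≤ n is fine)
and a letter → earliest-occurrence-position map; at node u with child edge
letter b, the letters in ls(u) \ ls(child_b) each yield one MAW a·u·b.
Choosing the *smallest* occurrence position of the prefix makes the
⟨(i, j), α⟩ tuples canonical. Length-2 MAWs (absent letter pairs) emerge at
the root and are kept out of the tuple stream because dev() needs a
non-empty infix; they are exposed separately and included in count-bound
checks. Total cost O(σn).

Avoided-word enumeration: absent candidates are exactly the MAW tuples
(of the queried length, or all); their three maximal factors occur by
minimality, so their counts come from tree loci. Occurring candidates are
the first-letter children of explicit internal nodes v (all four counts in
O(1): f_w = C(child), f_p = C(v), f_i = C(suffix-link(v)),
f_s = C(Child(suffix-link(v), b))); nodes with D(v) = k−1 in fixed-k mode,
every internal node of depth ≥ 2 in all-lengths mode — at most 2n−1
children in total. Output is sorted by deviation ascending with
lexicographic tie-break (the tie rule is a package choice; some
deterministic rule is needed for byte-identical reruns).

## Synthetic data

`random_sequence` draws i.i.d. uniform letters with numpy's PCG64 from a
recorded seed — it emulates the base-composition null the deviation is
measured against, and deliberately nothing else (no GC skew, no repeats,
no coding structure). Tests passing on it certify the combinatorics and
the statistic, not biological discovery on real genomes. The two
deterministic families are the worst-case constructions for MAW counts:
`maw_rich_word(σ, n)` (runs of the first letter separated by the other
letters; ≥ (σ−1)(σ−2)⌊n/(σ−1)⌋ − (σ−2) MAWs for σ ≥ 3, ≥ n−2 for σ = 2)
and `maw_dense_word(σ)` (block word whose prefixes y carry at least
((σ−2)² − σ)·⌊|y|/(2σ)⌋ MAWs of length exactly 3, meaningful for σ on the
order of √n and above). Both render a₁..a_σ as 'a'..'z' for σ ≤ 26 and as
integer tuples beyond.

## Testing and problem sizes

Correctness is defined against an independent brute-force oracle (sliding
window counts, explicit enumeration of all σᵏ words, and the MAW
definition applied directly); the oracle shares no code with the tree
path. The sweeps are exhaustive over all binary words of length ≤ 10 with
every 2 < k ≤ 11 and ρ ∈ {−0.01, −0.5, −2}, plus 100 seeded random DNA
words of length 200 at k = 3..8; MAW equivalence additionally covers the
extremal families up to σ = 16. Structural facts double as invariant
checks: absent avoided ⊆ MAWs, implicit-prefix words have dev ≥ 0,
|result| ≤ (σ+1)n − k + 1, and no avoided word is longer than the longest
repeated factor (deepest internal-node depth) plus 2.

The scaling check runs the full fixed-k pipeline (k = 8, ρ = −10, matching
the synthetic-benchmark setting) on random DNA of 1, 2 and 4 million
letters, one subprocess per size so each peak RSS is measured
independently, and asserts the 4× input costs well under the 16× of a
quadratic method in both time and memory (generous slack for machine
noise). Those sizes keep the whole suite in single-digit minutes on one
core; the implementation itself has handled the same pipeline at larger n,
limited only by ~1 KB/input-letter of Python object overhead.

## Known limitations

- Pure-Python constants: ~25–30 s and ~1 GB per million letters through
  the full pipeline — ample for bacterial genomes and chromosome arms, two
  orders of magnitude from the succinct-structure C++ implementations of
  the same algorithmics.
- Each FASTA record is analysed independently; there is no generalized
  tree over a multi-record file and no cross-record aggregation of counts.
- Overabundant words (dev ≥ threshold > 0) are not enumerated; the
  occurring-word pruning argument is one-sided and a symmetric query would
  need its own candidate set.
- No p-values: dev is a standardised deficit, and the factor-count events
  it conditions on are correlated in a sequence-dependent way.
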