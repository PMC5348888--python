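# avoidedwords

Find the **ρ-avoided words** of a DNA, protein or arbitrary-alphabet
sequence: words that occur markedly less often than their own sub-word
composition predicts — including words that do not occur at all.

Underrepresentation of specific short motifs is a biological signal.
Bacterial genomes deplete the self-complementary (palindromic) hexamers
targeted by their restriction endonucleases; functional non-coding elements
tolerate fewer locally underrepresented words than neutral sequence. This
package computes the complete set of such words for any length `k`, or for
all lengths at once, in time linear in the sequence length for a fixed
alphabet — not by enumerating the σᵏ possible words, but by walking an
annotated suffix tree and the sequence's minimal absent words.

## The statistic

For a word *w* with |*w*| > 2, let *f*(*w*) be its number of (possibly
overlapping) occurrences in the sequence *x*, and let *w*ₚ, *w*ₛ, *w*ᵢ be
the longest proper prefix, suffix and infix of *w*. The expected frequency
of *w* given its maximal proper factors is

    E(w) = f(w_p) · f(w_s) / f(w_i)          (E(w) = 0 if f(w_i) = 0)

and the standardised (χ²-style) deviation of observed from expected is

    dev(w) = (f(w) − E(w)) / max(√E(w), 1).

Given a threshold ρ < 0, *w* is **ρ-avoided** when dev(*w*) ≤ ρ. An avoided
word may be *occurring* (*f* > 0) or *absent* (*f* = 0); every absent
avoided word is necessarily a **minimal absent word** (MAW) — absent while
all of its proper factors occur. The enumeration exploits two pruning
facts: absent candidates come only from the MAW set, and an occurring
avoided word's longest proper prefix always labels an *explicit* suffix-tree
node (otherwise dev ≥ 0). This caps the candidates at (σ+1)·n − k + 1 and
yields the linear-time algorithm.

## Worked example

The 16-letter sequence `AGCGCGACGTCTGTGT` with `k = 3` and `ρ = −0.4`:

```sh
$ avoided-words -i example.fa -k 3 --rho -0.4
# avoided-words mode=fixed-k k=3 rho=-0.4
# sequence	word	status	f	E	dev
example	TCG	absent	0	0.750000	-0.750000
example	TGC	absent	0	0.666667	-0.666667
example	AGT	absent	0	0.500000	-0.500000
example	GAG	absent	0	0.500000	-0.500000
example	GCT	absent	0	0.500000	-0.500000
example	CGT	occurring	1	1.500000	-0.408248
example	GTG	occurring	1	1.500000	-0.408248
```

`CGT` occurs once but its factors predict E = f(CG)·f(GT)/f(G) = 3·3/6 =
1.5 expected occurrences, so dev = (1 − 1.5)/√1.5 = −0.408248: an
*occurring* avoided word. `AGT` never occurs although `AG`, `GT` and `G`
all do (E = 1·3/6 = 0.5, dev = −0.5): an *absent* avoided word, and a
minimal absent word. Rows are sorted by deviation, most avoided first.

The same from Python:

```python
from avoidedwords import Sequence, avoided_words

res = avoided_words(Sequence("example", "AGCGCGACGTCTGTGT"), k=3, rho=-0.4)
for r in res:
    print(r.word, r.status, r.f, r.E, round(r.dev, 6))
```

Other entry points: `all_avoided_words` (every length > 2 at once),
`compute_maws` (the minimal absent words themselves, as `⟨(i, j), α⟩`
tuples with w = x[i..j]·α), `build_suffix_tree` (the annotated tree, with
`occurrence_count`, `locate`, suffix links), generators for seeded random
sequences and for the extremal words that realise the worst-case MAW
counts, and `summarize_self_complementarity` to screen a result for
restriction-site-like palindromic words. `--gen-alphabet ACGT
--gen-length 20000 --gen-seed 7 --all-lengths --rho -1.5` on the CLI
reproduces a typical synthetic run (131 avoided words out of 36,409 MAWs
at n = 20,000).

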