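"""Avoided-word statistics and enumeration.

For a word ``w`` of length > 2 occurring-or-absent in a sequence ``x``,
its expected frequency is estimated from the counts of its maximal proper
factors (longest proper prefix ``w_p``, suffix ``w_s`` and infix ``w_i``):

    E(w) = f(w_p) * f(w_s) / f(w_i)        (0 when f(w_i) = 0)

and the standardised (chi-square style) deviation of observed from
expected frequency is

    dev(w) = (f(w) - E(w)) / max(sqrt(E(w)), 1).

Given a threshold rho < 0, ``w`` is *rho-avoided* when dev(w) <= rho.
Avoided words split into two classes, enumerated by separate routines:

* absent avoided words are always minimal absent words, so candidates come
  from the MAW tuple stream;
* occurring avoided words always have an explicit suffix-tree node for
  their longest proper prefix (words whose prefix sits on an edge have
  dev >= 0), so candidates are the first-letter children of explicit
  internal nodes, with all four counts read off C() annotations and the
  suffix link in constant time.

The fixed-length query and the all-lengths query share these routines.
Results are returned deviation-sorted (ties broken by word) in a
:class:`ResultSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ContractError, InputError
from .maw import MinimalAbsentWord, compute_maws
from .sequence import Sequence, Word
from .suffix_tree import SuffixTree, build_suffix_tree

OCCURRING = "occurring"
ABSENT = "absent"


@dataclass(frozen=True, slots=True)
class FactorCounts:
    """Observed frequencies of w and of its maximal proper factors."""

    f_w: int
    f_p: int
    f_s: int
    f_i: int

    def __post_init__(self):
        if min(self.f_w, self.f_p, self.f_s, self.f_i) < 0:
            raise ContractError("negative observed frequency")


def expected_frequency(counts: FactorCounts) -> float:
    """E(w) = f(w_p) f(w_s) / f(w_i), or 0 when the infix is absent."""
    if counts.f_i == 0:
        return 0.0
    return counts.f_p * counts.f_s / counts.f_i


def deviation(f_w: int, expected: float) -> float:
    """dev(w) = (f(w) - E(w)) / max(sqrt(E(w)), 1)."""
    if f_w < 0 or expected < 0:
        raise ContractError("frequencies must be non-negative")
    return (f_w - expected) / max(math.sqrt(expected), 1.0)


@dataclass(frozen=True, slots=True)
class AvoidedWordRecord:
    """One rho-avoided word with its statistics.

    ``counts`` keeps the exact integer factor frequencies, so ``E`` is
    reproducible as the rational f_p*f_s/f_i; ``dev`` is the float actually
    compared (unrounded) against rho.
    """

    word: Word
    f: int
    E: float
    dev: float
    status: str
    counts: FactorCounts

    @property
    def k(self) -> int:
        return len(self.word)


@dataclass
class ResultSet:
    """Deviation-ranked avoided words for one sequence and one query."""

    sequence_id: str
    rho: float
    k: int | None  # None in all-lengths mode
    records: list[AvoidedWordRecord] = field(default_factory=list)

    @property
    def all_lengths(self) -> bool:
        return self.k is None

    def words(self) -> list[Word]:
        return [r.word for r in self.records]

    def sort(self, by: str = "dev") -> "ResultSet":
        if by == "dev":
            self.records.sort(key=lambda r: (r.dev, r.word))
        elif by == "word":
            self.records.sort(key=lambda r: r.word)
        else:
            raise InputError(f"unknown sort key {by!r}")
        return self

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _check_query(k, rho) -> None:
    if rho >= 0:
        raise InputError(f"threshold rho must be negative, got {rho}")
    if k is not None:
        if int(k) != k or k <= 2:
            raise InputError(f"word length k must be an integer > 2, got {k}")


def _evaluate_absent(tree: SuffixTree, t: MinimalAbsentWord) -> AvoidedWordRecord:
    seq = tree.seq
    w_p = seq.word(t.i, t.j)
    w_i = seq.word(t.i + 1, t.j)
    w_s = seq.join(w_i, t.alpha)
    f_p = tree.occurrence_count(w_p)
    f_i = tree.occurrence_count(w_i)
    f_s = tree.occurrence_count(w_s)
    if not (f_p and f_i and f_s):
        raise ContractError("proper factors of a minimal absent word must occur")
    counts = FactorCounts(f_w=0, f_p=f_p, f_s=f_s, f_i=f_i)
    E = expected_frequency(counts)
    return AvoidedWordRecord(
        word=seq.join(w_p, t.alpha), f=0, E=E, dev=deviation(0, E),
        status=ABSENT, counts=counts,
    )


def absent_avoided_words(
    tree: SuffixTree,
    maws: Iterable[MinimalAbsentWord],
    k: int | None,
    rho: float,
) -> list[AvoidedWordRecord]:
    """Absent rho-avoided words among the MAW tuples: words of the requested
    length (all lengths when k is None) with dev <= rho.  All three proper
    maximal factors of a MAW occur, so their counts come from tree loci."""
    _check_query(k, rho)
    out = []
    for t in maws:
        if k is not None and t.length != k:
            continue
        rec = _evaluate_absent(tree, t)
        if rec.dev <= rho:
            out.append(rec)
    return out


def occurring_avoided_words(
    tree: SuffixTree, k: int | None, rho: float
) -> list[AvoidedWordRecord]:
    """Occurring rho-avoided words.

    Fixed-k mode scans explicit internal nodes v with D(v) = k - 1; the
    all-lengths mode scans every explicit internal node of word-depth >= 2.
    Each child edge with first letter ``b`` (sentinel edges skipped) yields
    the candidate w = L(v).b with f(w) = C(child), f(w_p) = C(v),
    f(w_i) = C(u) for u the suffix-link target of v, and
    f(w_s) = C(Child(u, b))."""
    _check_query(k, rho)
    tree.annotate()
    seq = tree.seq
    children, depth, count, slink = tree.children, tree.depth, tree.count, tree.slink
    min_leaf = tree.min_leaf
    sentinel = tree.sentinel
    alphabet = seq.alphabet
    out = []
    for v in tree.internal_nodes():
        d = depth[v]
        if k is not None:
            if d != k - 1:
                continue
        elif d < 2:
            continue
        u = slink[v]
        if u == -1:
            raise ContractError("internal non-root node lacks a suffix link")
        f_p = count[v]
        f_i = count[u]
        ukids = children[u]
        prefix = None
        for b in sorted(children[v]):
            if b == sentinel:
                continue
            f_w = count[children[v][b]]
            f_s = count[ukids[b]]
            counts = FactorCounts(f_w=f_w, f_p=f_p, f_s=f_s, f_i=f_i)
            E = expected_frequency(counts)
            dev = deviation(f_w, E)
            if dev <= rho:
                if prefix is None:
                    i0 = min_leaf[v]
                    prefix = seq.word(i0, i0 + d - 1)
                out.append(
                    AvoidedWordRecord(
                        word=seq.join(prefix, alphabet[b]),
                        f=f_w, E=E, dev=dev, status=OCCURRING, counts=counts,
                    )
                )
    return out


def avoided_words(
    seq: Sequence,
    k: int,
    rho: float,
    tree: SuffixTree | None = None,
    maws: list[MinimalAbsentWord] | None = None,
) -> ResultSet:
    """All rho-avoided words of length ``k`` in ``seq``, deviation-sorted.

    ``tree`` and ``maws`` may be passed to reuse precomputed structures
    when querying the same sequence repeatedly.  ``k`` larger than n + 1
    yields an empty result (no word of that length occurs and every MAW
    has length at most n + 1)."""
    _check_query(k, rho)
    if tree is None:
        tree = build_suffix_tree(seq)
    tree.annotate()
    if maws is None:
        maws = compute_maws(seq, tree)
    records = absent_avoided_words(tree, maws, k, rho)
    records += occurring_avoided_words(tree, k, rho)
    return ResultSet(sequence_id=seq.id, rho=rho, k=k, records=records).sort("dev")


def all_avoided_words(
    seq: Sequence,
    rho: float,
    tree: SuffixTree | None = None,
    maws: list[MinimalAbsentWord] | None = None,
) -> ResultSet:
    """All rho-avoided words of every length > 2, deviation-sorted; equals
    the union of the fixed-length queries over all k."""
    _check_query(None, rho)
    if tree is None:
        tree = build_suffix_tree(seq)
    tree.annotate()
    if maws is None:
        maws = compute_maws(seq, tree)
    records = absent_avoided_words(tree, maws, None, rho)
    records += occurring_avoided_words(tree, None, rho)
    return ResultSet(sequence_id=seq.id, rho=rho, k=None, records=records).sort("dev")


def longest_repeated_factor_length(tree: SuffixTree) -> int:
    """Length of the longest factor occurring at least twice: the greatest
    word-depth of an explicit internal node.  Bounds every avoided word's
    length minus 2."""
    tree.annotate()
    depth = tree.depth
    return max((depth[v] for v in tree.internal_nodes()), default=0)
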