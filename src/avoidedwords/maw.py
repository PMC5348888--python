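"""Minimal absent words (MAWs).

A word ``w`` is a minimal absent word of ``x`` when ``w`` does not occur in
``x`` but every proper factor of ``w`` does; equivalently, both maximal
proper factors ``w[:-1]`` and ``w[1:]`` occur while ``w`` itself is absent.

Enumeration works bottom-up on the annotated suffix tree.  Write a MAW as
``w = a . u . b`` with mid-part ``u`` (possibly empty).  Since some
occurrence of ``u`` is followed by ``b`` and the occurrence preceded by
``a`` is not, ``u`` is right-branching in ``x . $`` and therefore an
explicit node.  So it suffices to compute, for every node ``u``, the set
``ls(u)`` of letters immediately preceding occurrences of ``u``: the MAWs
with mid-part ``u`` are exactly

    { a u b : a in ls(u), b a child letter of u, a not in ls(child_b) }.

``ls`` sets are letter bitmasks merged child-to-parent in one postorder
pass; the total cost is O(sigma n).  MAWs of length 2 fall out of the same
scan at the root and are reported separately: the length >= 3 words carry
the tuple representation ``<(i, j), alpha>`` with ``w = x[i..j] . alpha``
(the avoided-words routines need exactly that form), where ``i`` is the
smallest occurrence position of ``x[i..j]`` so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .sequence import Sequence, Word
from .suffix_tree import SuffixTree


@dataclass(frozen=True, slots=True)
class MinimalAbsentWord:
    """Tuple form of a MAW of length >= 3: ``w = x[i..j] . alpha``.

    ``x[i..j]`` is the longest proper prefix of ``w`` (it occurs in x) and
    ``x[i+1..j] . alpha`` is its longest proper suffix (it occurs too).
    """

    i: int
    j: int
    alpha: object  # a letter

    @property
    def length(self) -> int:
        return self.j - self.i + 2

    def word(self, seq: Sequence) -> Word:
        return seq.join(seq.word(self.i, self.j), self.alpha)


def _maw_scan(tree: SuffixTree):
    """One bottom-up pass producing (tuples of length >= 3, length-2 words)."""
    seq = tree.seq
    n = seq.n
    x = seq.ranks
    children, start, depth = tree.children, tree.start, tree.depth
    suffix_index = tree.suffix_index
    s = tree.s
    sentinel = tree.sentinel

    nn = tree.num_nodes
    ls = [0] * nn  # bitmask of left-extension letters
    lpos = [None] * nn  # {left letter rank: min occurrence position of node word}

    # children in rank order -> reverse preorder is a postorder
    stack = [0]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        kids = children[v]
        if kids:
            for key in sorted(kids, reverse=True):
                stack.append(kids[key])

    tuples: list[MinimalAbsentWord] = []
    pairs: list[Word] = []
    alphabet = seq.alphabet

    for v in reversed(order):
        kids = children[v]
        if not kids:
            p = suffix_index[v]
            if p > 0:
                a = x[p - 1]
                ls[v] = 1 << a
                lpos[v] = {a: p}
            else:
                lpos[v] = {}
            continue
        mask = 0
        merged: dict = {}
        for w in kids.values():
            mask |= ls[w]
            sub = lpos[w]
            if len(sub) > len(merged):
                merged, sub = sub, merged
            for a, p in sub.items():
                if a not in merged or p < merged[a]:
                    merged[a] = p
        ls[v] = mask
        lpos[v] = merged
        # emit MAWs with mid-part L(v) before freeing the child dicts
        d = depth[v]
        for b in sorted(kids):
            if b == sentinel:
                continue
            w = kids[b]
            # letters preceding u but never preceding u.b  ->  MAWs a.u.b
            miss = mask & ~ls[w]
            a = 0
            while miss:
                if miss & 1:
                    if v == 0:
                        pairs.append(seq.join(alphabet[a], alphabet[b]))
                    else:
                        p = merged[a]
                        tuples.append(
                            MinimalAbsentWord(i=p - 1, j=p + d - 1, alpha=alphabet[b])
                        )
                miss >>= 1
                a += 1
            lpos[w] = None  # free child dict

    tuples.sort(key=lambda t: (t.length, t.i, t.alpha))
    pairs.sort()
    return tuples, pairs


def compute_maws(seq: Sequence, tree: SuffixTree | None = None) -> list[MinimalAbsentWord]:
    """All minimal absent words of ``seq`` of length >= 3, as tuples, sorted
    by (length, start position, extension letter)."""
    if tree is None:
        from .suffix_tree import build_suffix_tree

        tree = build_suffix_tree(seq)
    tree.annotate()
    tuples, _ = _maw_scan(tree)
    return tuples


def absent_pairs(seq: Sequence, tree: SuffixTree | None = None) -> list[Word]:
    """Minimal absent words of length exactly 2 (absent letter pairs), as
    words.  Kept out of the tuple stream: the deviation statistic is defined
    only for words longer than 2."""
    if tree is None:
        from .suffix_tree import build_suffix_tree

        tree = build_suffix_tree(seq)
    tree.annotate()
    _, pairs = _maw_scan(tree)
    return pairs


def maws_of_length(maws, k: int) -> list[MinimalAbsentWord]:
    """The sub-collection of MAW tuples of length ``k`` (= j - i + 2)."""
    if k <= 2:
        raise InputError("MAW tuples exist only for lengths k > 2")
    return [t for t in maws if t.length == k]


def write_maw_words(maws, seq: Sequence, path) -> None:
    """Export MAWs as plain text, one word per line (interoperability with
    published MAW tools)."""
    with open(path, "w") as fh:
        for t in maws:
            w = t.word(seq)
            fh.write(w if isinstance(w, str) else ",".join(map(str, w)))
            fh.write("\n")
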