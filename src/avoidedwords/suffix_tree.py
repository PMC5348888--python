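"""Annotated suffix tree of a sequence.

The tree is the compact trie of all suffixes of ``x . $`` where ``$`` is a
unique sentinel outside the alphabet, so every suffix of ``x`` ends at its
own leaf.  Construction is Ukkonen's online algorithm (amortised linear for
a fixed-size alphabet), storing nodes in flat parallel arrays with
children held in per-node dicts keyed by first-edge-letter rank.

Annotations filled by :meth:`SuffixTree.annotate` (a single depth-first
pass, children visited in letter-rank order so everything downstream is
deterministic):

``depth[v]``      word-depth D(v): number of sentinel-free letters on the
                  root-to-v path (for leaves the trailing sentinel is not
                  counted, so the leaf of suffix ``i`` has depth ``n - i``).
``count[v]``      C(v): number of terminal nodes in the subtree of v whose
                  suffix index is < n, i.e. the observed frequency f(L(v))
                  of the sentinel-free path label.
``min_leaf[v]``   smallest terminal index below v, so
                  L(v) = x[min_leaf[v] .. min_leaf[v] + depth[v] - 1].
``parent[v]``     parent link.
``suffix_index[v]`` starting position of the suffix, for leaves (-1 else).

Occurrence counts of arbitrary factors are read off the tree through
:meth:`locate` / :meth:`occurrence_count`: the count of a word located at
an implicit position on edge (u, v) is C(v), not C(u).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError, InputError
from .sequence import Sequence, Word

_INF = 1 << 60


@dataclass(frozen=True, slots=True)
class Locus:
    """Position of a word in the tree: the explicit node at or immediately
    below it, and the number of letters located.  ``explicit`` is true when
    the word ends exactly at ``node``."""

    node: int
    depth: int
    explicit: bool


class SuffixTree:
    """Suffix tree of ``seq`` with occurrence-count annotation."""

    ROOT = 0

    def __init__(self, seq: Sequence):
        self.seq = seq
        self.n = seq.n
        self.sentinel = seq.sigma  # rank one past the real alphabet
        self.s = seq.ranks + [self.sentinel]
        self._build()
        self._annotated = False

    # ------------------------------------------------------------------
    # construction (Ukkonen)
    # ------------------------------------------------------------------
    def _build(self) -> None:
        s = self.s
        m = len(s)  # n + 1 with sentinel
        start = [0]
        end = [0]
        children: list = [{}]
        slink = [-1]

        def new_node(st: int, en: int) -> int:
            start.append(st)
            end.append(en)
            children.append(None)
            slink.append(-1)
            return len(start) - 1

        active_node = 0
        active_edge = 0  # index into s of the first letter of the active edge
        active_len = 0
        remainder = 0

        for i in range(m):
            c = s[i]
            remainder += 1
            last_internal = -1
            while remainder > 0:
                if active_len == 0:
                    active_edge = i
                kids = children[active_node]
                nxt = kids.get(s[active_edge]) if kids else None
                if nxt is None:
                    leaf = new_node(i, _INF)
                    if kids is None:
                        kids = children[active_node] = {}
                    kids[s[active_edge]] = leaf
                    if last_internal != -1:
                        slink[last_internal] = active_node
                        last_internal = -1
                else:
                    edge_len = min(end[nxt], i + 1) - start[nxt]
                    if active_len >= edge_len:
                        active_edge += edge_len
                        active_len -= edge_len
                        active_node = nxt
                        continue
                    if s[start[nxt] + active_len] == c:
                        active_len += 1
                        if last_internal != -1:
                            slink[last_internal] = active_node
                            last_internal = -1
                        break
                    split = new_node(start[nxt], start[nxt] + active_len)
                    children[active_node][s[active_edge]] = split
                    leaf = new_node(i, _INF)
                    start[nxt] += active_len
                    children[split] = {c: leaf, s[start[nxt]]: nxt}
                    if last_internal != -1:
                        slink[last_internal] = split
                    last_internal = split
                remainder -= 1
                if active_node == 0 and active_len > 0:
                    active_len -= 1
                    active_edge = i - remainder + 1
                elif active_node != 0:
                    active_node = slink[active_node] if slink[active_node] != -1 else 0

        for v in range(len(start)):
            if end[v] == _INF:
                end[v] = m
        self.start = start
        self.end = end
        self.children = children
        self.slink = slink

    # ------------------------------------------------------------------
    # annotation
    # ------------------------------------------------------------------
    def annotate(self) -> "SuffixTree":
        """Fill D, C, parent, smallest terminal index and suffix indices by
        one iterative depth-first traversal (children in letter-rank order).
        Idempotent; returns self."""
        if self._annotated:
            return self
        nn = len(self.start)
        n, m = self.n, self.n + 1
        start, end, children = self.start, self.end, self.children
        depth = [0] * nn
        count = [0] * nn
        parent = [-1] * nn
        min_leaf = [_INF] * nn
        suffix_index = [-1] * nn

        stack = [0]
        order = []  # preorder, children in letter-rank order
        while stack:
            v = stack.pop()
            order.append(v)
            kids = children[v]
            if kids:
                for key in sorted(kids, reverse=True):
                    w = kids[key]
                    parent[w] = v
                    fd = depth[v] + (end[w] - start[w])
                    if children[w]:
                        depth[w] = fd
                    else:  # leaf: do not count the trailing sentinel
                        si = m - fd
                        suffix_index[w] = si
                        depth[w] = n - si
                    stack.append(w)
        # bottom-up: reverse preorder is a valid postorder for accumulation
        for v in reversed(order):
            kids = children[v]
            if kids:
                c = 0
                ml = _INF
                for w in kids.values():
                    c += count[w]
                    if min_leaf[w] < ml:
                        ml = min_leaf[w]
                count[v] = c
                min_leaf[v] = ml
            else:
                si = suffix_index[v]
                if si < n:  # the sentinel-only leaf does not count
                    count[v] = 1
                    min_leaf[v] = si

        self.depth = depth
        self.count = count
        self.parent = parent
        self.min_leaf = min_leaf
        self.suffix_index = suffix_index
        self._annotated = True
        return self

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def num_nodes(self) -> int:
        return len(self.start)

    @property
    def num_edges(self) -> int:
        return len(self.start) - 1

    def child(self, v: int, letter) -> int | None:
        """Child(v, letter): explicit node below v along the edge whose label
        starts with ``letter`` (a letter of the sequence alphabet)."""
        try:
            r = self.seq.rank(letter)
        except KeyError:
            return None
        kids = self.children[v]
        return kids.get(r) if kids else None

    def path_label(self, v: int) -> Word:
        """L(v) for an annotated tree (sentinel-free)."""
        i = self.min_leaf[v]
        return self.seq.word(i, i + self.depth[v] - 1)

    def locate(self, w: Word) -> Locus | None:
        """Locus of word ``w`` (explicit or implicit), or None if absent.

        Descends from the root comparing edge letters left to right; costs
        O(|w|) dictionary lookups and letter comparisons.
        """
        if len(w) == 0:
            raise InputError("cannot locate the empty word")
        rw = self.seq.rank_word(w)
        if rw is None:
            return None
        s, start, end, children = self.s, self.start, self.end, self.children
        v = 0
        i = 0
        k = len(rw)
        while True:
            kids = children[v]
            nxt = kids.get(rw[i]) if kids else None
            if nxt is None:
                return None
            j = start[nxt]
            stop = end[nxt]
            while j < stop and i < k:
                if s[j] != rw[i]:
                    return None
                j += 1
                i += 1
            if i == k:
                # a locus just before the trailing sentinel of a leaf edge is
                # the end of a sentinel-free terminal label, hence explicit
                explicit = j == stop or s[j] == self.sentinel
                return Locus(node=nxt, depth=k, explicit=explicit)
            v = nxt

    def occurrence_count(self, w: Word) -> int:
        """Observed frequency f(w): number of (overlapping) occurrences of
        ``w`` in x; 0 if absent. Requires an annotated tree."""
        loc = self.locate(w)
        return self.count[loc.node] if loc is not None else 0

    def suffix_link(self, v: int) -> int:
        """Suffix-link target of a non-root internal explicit node: the node
        path-labelled L(v) minus its first letter."""
        if v == self.ROOT or self.is_leaf(v):
            raise ContractError("suffix link is defined only for non-root internal nodes")
        u = self.slink[v]
        if u == -1:
            raise ContractError("missing suffix link on internal node")
        return u

    def internal_nodes(self):
        """All explicit internal nodes except the root, in index order."""
        children = self.children
        return (v for v in range(1, len(self.start)) if children[v])


def build_suffix_tree(seq: Sequence, annotate: bool = True) -> SuffixTree:
    """Build (and by default annotate) the suffix tree of ``seq``."""
    tree = SuffixTree(seq)
    if annotate:
        tree.annotate()
    return tree
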