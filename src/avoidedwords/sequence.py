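"""Sequences over a finite ordered alphabet.

A :class:`Sequence` wraps an identifier and a word ``x`` of length ``n``
over the alphabet of distinct letters actually present in it.  Internally
every letter is rank-mapped to an integer in ``0..sigma-1`` following the
natural (sorted) order of the letters, which is the integer-alphabet model
all downstream algorithms operate on.  Letters are usually characters of a
``str`` (DNA, protein), but any hashable, orderable tokens are accepted so
that alphabets larger than 26 letters can be represented as tuples of ints.
"""

from __future__ import annotations

from typing import Sequence as PySequence, Union

from .errors import InputError

Word = Union[str, tuple]


class Sequence:
    """An identified word over a finite ordered alphabet.

    Parameters
    ----------
    id : str
        Label of the sequence (FASTA header word, generator tag, ...).
    letters : str or tuple
        The word ``x`` itself. Must be non-empty.
    uppercase : bool
        If true and ``letters`` is a string, normalise to upper case.
    """

    __slots__ = ("id", "letters", "alphabet", "ranks", "_rank_of")

    def __init__(self, id: str, letters: Word, uppercase: bool = False):
        if len(letters) == 0:
            raise InputError(f"sequence {id!r} is empty")
        if uppercase and isinstance(letters, str):
            letters = letters.upper()
        self.id = id
        self.letters = letters
        # rank mapping: bijection distinct letters -> 0..sigma-1 in sorted order
        self.alphabet = tuple(sorted(set(letters)))
        self._rank_of = {a: r for r, a in enumerate(self.alphabet)}
        rank_of = self._rank_of
        self.ranks = [rank_of[a] for a in letters]

    @property
    def n(self) -> int:
        return len(self.letters)

    @property
    def sigma(self) -> int:
        return len(self.alphabet)

    def rank(self, letter) -> int:
        """Rank of a single letter; raises KeyError for foreign letters."""
        return self._rank_of[letter]

    def rank_word(self, w: Word):
        """Rank-map an arbitrary word, or None if it uses foreign letters."""
        rank_of = self._rank_of
        try:
            return [rank_of[a] for a in w]
        except KeyError:
            return None

    def word(self, i: int, j: int) -> Word:
        """The factor ``x[i..j]`` (0-based, inclusive), as letters."""
        sub = self.letters[i : j + 1]
        return sub if isinstance(self.letters, str) else tuple(sub)

    def join(self, *parts) -> Word:
        """Concatenate letter chunks in the sequence's letter type."""
        if isinstance(self.letters, str):
            return "".join(parts)
        out = []
        for p in parts:
            out.extend(p if isinstance(p, (tuple, list)) else (p,))
        return tuple(out)

    def letter(self, rank: int):
        return self.alphabet[rank]

    def __len__(self) -> int:
        return len(self.letters)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        head = self.letters[:40]
        if not isinstance(head, str):
            head = ",".join(map(str, head))
        return f"Sequence(id={self.id!r}, n={self.n}, sigma={self.sigma}, x={head}...)"
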