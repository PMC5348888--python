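"""Synthetic sequences: seeded random words and extremal MAW-rich families.

``random_sequence`` draws i.i.d. uniform letters with numpy's default
PRNG (PCG64), reproducible from the seed recorded in the sequence id.

The two deterministic families realise the worst-case constructions that
make the O(sigma n) bound on minimal-absent-word counts tight:

* :func:`maw_rich_word` — runs of the first letter separated by single
  distinct letters; it packs Omega(sigma n) MAWs overall.
* :func:`maw_dense_word` — a block concatenation whose prefixes carry
  Omega(sigma n) MAWs of the fixed length 3 (needs sigma >= 3; the bound
  is meaningful for sigma on the order of sqrt(n) or larger).

Letters a_1..a_sigma render as 'a', 'b', 'c', ... for sigma <= 26; larger
alphabets use integer tokens (the sequence is then a tuple of ints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .sequence import Sequence

_ASCII = "abcdefghijklmnopqrstuvwxyz"


def _letters(sigma: int):
    """a_1..a_sigma as printable letters (sigma <= 26) or int tokens."""
    if sigma <= 26:
        return _ASCII[:sigma]
    return tuple(range(1, sigma + 1))


@dataclass(frozen=True)
class GeneratorConfig:
    """Recipe for a reproducible random sequence."""

    alphabet: str | tuple
    n: int
    seed: int

    def __post_init__(self):
        if len(self.alphabet) < 1:
            raise InputError("alphabet must contain at least one letter")
        if self.n < 1:
            raise InputError("sequence length must be positive")


def random_sequence(cfg: GeneratorConfig) -> Sequence:
    """I.i.d. uniform letters over ``cfg.alphabet``, reproducible from the
    seed, which is recorded in the sequence id."""
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, len(cfg.alphabet), size=cfg.n)
    alpha = cfg.alphabet
    if isinstance(alpha, str):
        lut = np.frombuffer(alpha.encode("ascii"), dtype=np.uint8)
        letters = lut[idx].tobytes().decode("ascii")
    else:
        letters = tuple(alpha[i] for i in idx)
    sid = f"random_s{len(alpha)}_n{cfg.n}_seed{cfg.seed}"
    return Sequence(id=sid, letters=letters)


def maw_rich_word(sigma: int, n: int) -> Sequence:
    """Length-n word over sigma letters with Omega(sigma n) minimal absent
    words.

    sigma = 2 gives  b a^(n-2) b.  For sigma >= 3 the word is
    a_2 a_1^k a_3 a_1^k ... a_sigma a_1^k a_1^m  with
    k = floor(n / (sigma - 1)) - 1 and m = n - (sigma - 1)(k + 1); it has
    at least (sigma-1)(sigma-2) floor(n/(sigma-1)) - (sigma-2) MAWs
    (counting the absent letter pairs)."""
    if sigma < 2:
        raise InputError("need at least two letters")
    if sigma > n:
        raise InputError("alphabet size cannot exceed the word length")
    letters = _letters(sigma)
    a1 = letters[0]
    if sigma == 2:
        parts = [letters[1], a1 * (n - 2) if isinstance(a1, str) else (a1,) * (n - 2), letters[1]]
    else:
        k = n // (sigma - 1) - 1
        m = n - (sigma - 1) * (k + 1)
        run = a1 * k if isinstance(a1, str) else (a1,) * k
        parts = []
        for i in range(1, sigma):
            parts.append(letters[i])
            parts.append(run)
        parts.append(a1 * m if isinstance(a1, str) else (a1,) * m)
    if isinstance(letters, str):
        x = "".join(parts)
    else:
        x = tuple(t for p in parts for t in (p if isinstance(p, tuple) else (p,)))
    assert len(x) == n
    return Sequence(id=f"maw_rich_s{sigma}_n{n}", letters=x)


def maw_dense_word(sigma: int, n: int | None = None) -> Sequence:
    """Prefix of length n of the block word B_1 B_2 ... B_(sigma-1), where
    B_i = a_(i+1) a_i a_(i+2) a_i ... a_sigma a_i  (|B_i| = 2 (sigma - i)).

    The full word has length sigma (sigma - 1); its prefixes y longer than
    2 (sigma - 1) have at least ((sigma-2)^2 - sigma) * floor(|y| / (2 sigma))
    minimal absent words of length 3."""
    if sigma < 3:
        raise InputError("the block construction needs at least three letters")
    full = sigma * (sigma - 1)
    if n is None:
        n = full
    if n > full:
        raise InputError(f"the block word has length {full}; cannot take a prefix of {n}")
    if n < 1:
        raise InputError("sequence length must be positive")
    letters = _letters(sigma)
    blocks = []
    for i in range(1, sigma):  # B_i, 1-based
        for j in range(i + 1, sigma + 1):
            blocks.append(letters[j - 1])
            blocks.append(letters[i - 1])
    prefix = blocks[:n]
    x = "".join(prefix) if isinstance(letters, str) else tuple(prefix)
    assert len(x) == n
    return Sequence(id=f"maw_dense_s{sigma}_n{n}", letters=x)
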