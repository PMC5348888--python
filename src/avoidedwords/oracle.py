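"""Brute-force reference implementations, for testing only.

Everything here works by sliding-window scans and explicit enumeration and
shares no code with the suffix-tree, MAW or avoided-words modules, so
agreement between the two routes is meaningful evidence of correctness.
Performance is a non-goal.
"""

from __future__ import annotations

import math
from itertools import product

from .errors import InputError

_ENUM_LIMIT = 2_000_000


def naive_count(x, w) -> int:
    """Number of (possibly overlapping) occurrences of ``w`` in ``x`` by a
    sliding-window scan."""
    if len(w) == 0:
        raise InputError("empty pattern")
    m = len(w)
    return sum(1 for i in range(len(x) - m + 1) if x[i : i + m] == w)


def _factor_counts(x, length: int) -> dict:
    """Counts of every factor of ``x`` of the given length (sliding window)."""
    table: dict = {}
    for i in range(len(x) - length + 1):
        f = x[i : i + length]
        table[f] = table.get(f, 0) + 1
    return table


def _letters(x):
    return sorted(set(x))


def _words_of_length(letters, k: int):
    if isinstance(letters[0], str):
        return ("".join(p) for p in product(letters, repeat=k))
    return product(letters, repeat=k)


def brute_force_dev_table(x, k: int) -> dict:
    """For every word w of length k over the distinct letters of x:
    ``w -> (f, E, dev, f_p, f_s, f_i)`` computed by naive counting."""
    letters = _letters(x)
    if len(letters) ** k > _ENUM_LIMIT:
        raise InputError("enumeration too large for the brute-force oracle")
    ck = _factor_counts(x, k) if k <= len(x) else {}
    ck1 = _factor_counts(x, k - 1) if k - 1 <= len(x) else {}
    ck2 = _factor_counts(x, k - 2) if k - 2 <= len(x) else {}
    table = {}
    for w in _words_of_length(letters, k):
        f = ck.get(w, 0)
        f_p = ck1.get(w[:-1], 0)
        f_s = ck1.get(w[1:], 0)
        f_i = ck2.get(w[1:-1], 0)
        E = f_p * f_s / f_i if f_i > 0 else 0.0
        dev = (f - E) / max(math.sqrt(E), 1.0)
        table[w] = (f, E, dev, f_p, f_s, f_i)
    return table


def brute_force_avoided(x, k: int, rho: float) -> dict:
    """Words of length k with dev <= rho: ``w -> (f, E, dev)``."""
    if rho >= 0:
        raise InputError("rho must be negative")
    if k <= 2:
        raise InputError("k must exceed 2")
    return {
        w: (f, E, dev)
        for w, (f, E, dev, *_rest) in brute_force_dev_table(x, k).items()
        if dev <= rho
    }


def brute_force_maws(x, max_len: int) -> set:
    """All minimal absent words of ``x`` of length 2..max_len.

    Direct application of the definition: w is minimally absent when w is
    absent while both maximal proper factors w[:-1] and w[1:] occur (every
    proper factor of w is a factor of one of those two).  Candidates are
    occurring (m-1)-mers extended by each letter, which enumerates every
    word whose longest proper prefix occurs."""
    if max_len > len(x) + 1:
        raise InputError("no minimal absent word is longer than n + 1")
    letters = _letters(x)
    out = set()
    join_str = isinstance(x, str)
    for m in range(2, max_len + 1):
        occurring_prev = _factor_counts(x, m - 1)
        occurring_m = _factor_counts(x, m) if m <= len(x) else {}
        for u in occurring_prev:
            for a in letters:
                w = u + a if join_str else u + (a,)
                if w not in occurring_m and w[1:] in occurring_prev:
                    out.add(w)
    return out
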