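"""FASTA input, tab-separated result output, and the self-complementarity
(restriction-site palindrome) utility.

The FASTA reader is deliberately strict — sequence data before the first
header or a header with no sequence is an error reported with its line
number — because silently skipping malformed records would change every
downstream statistic.  Each record becomes an independent
:class:`~avoidedwords.sequence.Sequence`; record ids are the header text up
to the first whitespace.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable

from Bio.Seq import reverse_complement

from .avoided import ResultSet
from .errors import InputError
from .sequence import Sequence

_DNA = set("ACGT")


def read_fasta(path, uppercase: bool = False, skip_n: bool = False) -> list[Sequence]:
    """Parse a (Multi)FASTA file into one Sequence per record.

    Line breaks inside a record are joined; ``skip_n`` drops records
    containing the letter N (after optional uppercasing)."""
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                name = header.split()[0] if header else f"record{len(records) + 1}"
                records.append((name, []))
            else:
                if not records:
                    raise InputError(
                        f"{path}: line {lineno}: sequence data before the first FASTA header"
                    )
                records[-1][1].append(line)
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    out = []
    for name, chunks in records:
        if not chunks:
            raise InputError(f"{path}: record {name!r} has no sequence")
        letters = "".join(chunks)
        if uppercase:
            letters = letters.upper()
        if skip_n and "N" in letters:
            continue
        out.append(Sequence(id=name, letters=letters))
    return out


def write_fasta(seqs: Iterable[Sequence], path, width: int = 70) -> None:
    """Write sequences as FASTA (string alphabets only)."""
    with open(path, "w") as fh:
        for seq in seqs:
            if not isinstance(seq.letters, str):
                raise InputError("only string alphabets can be written as FASTA")
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.n, width):
                fh.write(seq.letters[i : i + width] + "\n")


def format_results(
    results: Iterable[ResultSet],
    k: int | None = None,
    rho: float | None = None,
    seed: int | None = None,
) -> str:
    """Render result sets as the tab-separated report text.

    Comment lines record the query; data rows are
    ``sequence_id  word  status  f  E  dev`` with E and dev printed to six
    decimals (records were thresholded on the unrounded deviation)."""
    buf = _io.StringIO()
    mode = "all-lengths" if k is None else "fixed-k"
    buf.write(f"# avoided-words mode={mode}")
    if k is not None:
        buf.write(f" k={k}")
    if rho is not None:
        buf.write(f" rho={rho}")
    if seed is not None:
        buf.write(f" seed={seed}")
    buf.write("\n# sequence\tword\tstatus\tf\tE\tdev\n")
    for res in results:
        for r in res.records:
            w = r.word if isinstance(r.word, str) else ",".join(map(str, r.word))
            buf.write(
                f"{res.sequence_id}\t{w}\t{r.status}\t{r.f}\t{r.E:.6f}\t{r.dev:.6f}\n"
            )
    return buf.getvalue()


def write_results(results, path, k=None, rho=None, seed=None) -> None:
    """Write the TSV report; the text is built fully before the file is
    opened, so a failure never leaves a partial output file."""
    text = format_results(results, k=k, rho=rho, seed=seed)
    with open(path, "w") as fh:
        fh.write(text)


def parse_results(text: str) -> list[tuple]:
    """Parse a report back into (sequence_id, word, status, f, E, dev) rows."""
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        sid, w, status, f, E, dev = line.split("\t")
        rows.append((sid, w, status, int(f), float(E), float(dev)))
    return rows


# ----------------------------------------------------------------------
# self-complementary (palindromic) DNA words — restriction-site avoidance
# ----------------------------------------------------------------------

def is_self_complementary(w: str) -> bool:
    """True iff the DNA word equals its reverse complement (requires even
    length; type-II restriction endonuclease target sites have this form)."""
    if not w or set(w) - _DNA:
        raise InputError(f"self-complementarity is defined over A/C/G/T only: {w!r}")
    if len(w) % 2:
        return False
    return w == reverse_complement(w)


@dataclass(frozen=True)
class SelfComplementaritySummary:
    total: int
    self_complementary: int
    top_m: int
    top_m_self_complementary: int

    @property
    def top_m_fraction(self) -> float:
        return self.top_m_self_complementary / self.top_m if self.top_m else 0.0


def summarize_self_complementarity(
    result: ResultSet, top_m: int | None = None
) -> SelfComplementaritySummary:
    """Count self-complementary words in a deviation-sorted result, overall
    and among the ``top_m`` most avoided (default: all of them)."""
    records = sorted(result.records, key=lambda r: (r.dev, r.word))
    flags = [is_self_complementary(r.word) for r in records]
    m = len(flags) if top_m is None else min(top_m, len(flags))
    return SelfComplementaritySummary(
        total=len(flags),
        self_complementary=sum(flags),
        top_m=m,
        top_m_self_complementary=sum(flags[:m]),
    )
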