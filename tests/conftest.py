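import itertools

import pytest

from avoidedwords import Sequence, build_suffix_tree

EXAMPLE_WORD = "AGCGCGACGTCTGTGT"


@pytest.fixture(scope="session")
def example_seq():
    return Sequence(id="example", letters=EXAMPLE_WORD)


@pytest.fixture(scope="session")
def example_tree(example_seq):
    return build_suffix_tree(example_seq)


def binary_words(max_len, letters="ab"):
    """Every word over ``letters`` of length 1..max_len."""
    for n in range(1, max_len + 1):
        for tup in itertools.product(letters, repeat=n):
            yield "".join(tup)
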