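"""Deviation statistics and avoided-word enumeration."""

import math
import random
from fractions import Fraction

import pytest

from avoidedwords import (
    ABSENT,
    OCCURRING,
    ContractError,
    FactorCounts,
    GeneratorConfig,
    InputError,
    Sequence,
    all_avoided_words,
    avoided_words,
    build_suffix_tree,
    compute_maws,
    deviation,
    expected_frequency,
    longest_repeated_factor_length,
    maw_rich_word,
    random_sequence,
)
from avoidedwords.oracle import brute_force_avoided, brute_force_dev_table


class TestStatistics:
    @pytest.mark.parametrize(
        "fp,fs,fi,expected",
        [(3, 3, 6, 1.5), (1, 3, 6, 0.5), (5, 2, 0, 0.0), (1, 1, 7, 1 / 7)],
    )
    def test_expected_frequency(self, fp, fs, fi, expected):
        c = FactorCounts(f_w=0, f_p=fp, f_s=fs, f_i=fi)
        assert expected_frequency(c) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ContractError):
            FactorCounts(f_w=-1, f_p=0, f_s=0, f_i=0)

    @pytest.mark.parametrize(
        "f,E,expected",
        [(1, 1.5, -0.408248), (0, 0.5, -0.5), (4, 4.0, 0.0), (7, 7.0, 0.0)],
    )
    def test_deviation(self, f, E, expected):
        assert deviation(f, E) == pytest.approx(expected, abs=5e-7)

    def test_deviation_denominator_floor(self):
        """Below E = 1 the denominator is clamped at 1."""
        assert deviation(0, 0.25) == -0.25
        assert deviation(0, 4.0) == -2.0


class TestWorkedExample:
    """x = AGCGCGACGTCTGTGT, k = 3, rho = -0.4."""

    def test_occurring_and_absent_records(self, example_seq):
        res = avoided_words(example_seq, 3, -0.4)
        rec = {r.word: r for r in res}
        cgt, agt = rec["CGT"], rec["AGT"]
        assert cgt.status == OCCURRING and cgt.f == 1
        assert cgt.E == pytest.approx(1.5)
        assert round(cgt.dev, 6) == -0.408248
        assert agt.status == ABSENT and agt.f == 0
        assert agt.E == pytest.approx(0.5)
        assert agt.dev == -0.5

    def test_sorted_by_deviation_then_word(self, example_seq):
        res = avoided_words(example_seq, 3, -0.4)
        devs = [r.dev for r in res]
        assert devs == sorted(devs)
        assert res.words().index("AGT") < res.words().index("CGT")


class TestQueryContracts:
    def test_rho_must_be_negative(self, example_seq):
        with pytest.raises(InputError):
            avoided_words(example_seq, 3, 0.0)
        with pytest.raises(InputError):
            all_avoided_words(example_seq, 0.5)

    def test_k_must_exceed_two(self, example_seq):
        with pytest.raises(InputError):
            avoided_words(example_seq, 2, -0.5)

    def test_k_beyond_n_plus_one_is_empty(self, example_seq):
        assert len(avoided_words(example_seq, example_seq.n + 2, -0.001)) == 0

    def test_huge_negative_rho_empty(self, example_seq):
        """|dev| of any candidate is bounded by sqrt(n), so an extreme
        threshold excludes everything."""
        assert len(all_avoided_words(example_seq, -1e6)) == 0

    def test_rho_monotonicity(self, example_seq):
        r1 = set(avoided_words(example_seq, 3, -2.0).words())
        r2 = set(avoided_words(example_seq, 3, -0.5).words())
        r3 = set(avoided_words(example_seq, 3, -0.01).words())
        assert r1 <= r2 <= r3

    def test_boundary_dev_equal_rho_included(self, example_seq):
        res = avoided_words(example_seq, 3, -0.5)
        assert "AGT" in res.words()  # dev == rho exactly


class TestRecordInvariants:
    def test_counts_chain_and_exact_rational(self):
        """f <= f_p, f <= f_s, f_p <= f_i, f_s <= f_i on every emitted
        record, and E reproduces exactly from the integer counts."""
        rng = random.Random(5)
        for _ in range(20):
            x = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 120)))
            res = all_avoided_words(Sequence("x", x), -0.05)
            for r in res:
                c = r.counts
                assert r.f == c.f_w <= c.f_p <= c.f_i
                assert c.f_w <= c.f_s <= c.f_i
                # E is the float image of the exact rational f_p f_s / f_i
                assert r.E == float(Fraction(c.f_p * c.f_s, c.f_i))
                assert (r.status == ABSENT) == (r.f == 0)
                assert r.dev <= res.rho

    def test_absent_records_are_maws(self):
        rng = random.Random(6)
        for _ in range(10):
            x = "".join(rng.choice("ab") for _ in range(rng.randint(5, 40)))
            seq = Sequence("x", x)
            maw_set = {t.word(seq) for t in compute_maws(seq)}
            res = all_avoided_words(seq, -0.01)
            for r in res:
                if r.status == ABSENT:
                    assert r.word in maw_set


class TestAgainstOracle:
    def test_fixed_k_random_dna(self):
        rng = random.Random(1)
        for _ in range(15):
            n = rng.randint(20, 400)
            x = "".join(rng.choice("ACGT") for _ in range(n))
            seq = Sequence("x", x)
            tree = build_suffix_tree(seq)
            for k in (3, 4, 5):
                got = {r.word: (r.f, round(r.dev, 9)) for r in avoided_words(seq, k, -0.1, tree=tree)}
                want = {w: (f, round(d, 9)) for w, (f, E, d) in brute_force_avoided(x, k, -0.1).items()}
                assert got == want, (x, k)

    def test_all_lengths_equals_union_over_k(self):
        """Definitional identity between the all-lengths query and the
        union of fixed-length queries."""
        for seed in range(50):
            seq = random_sequence(GeneratorConfig("ACGT", 200, seed))
            tree = build_suffix_tree(seq)
            maws = compute_maws(seq, tree)
            allres = {r.word: r.dev for r in all_avoided_words(seq, -0.4, tree=tree, maws=maws)}
            union = {}
            kmax = longest_repeated_factor_length(tree) + 2
            for k in range(3, kmax + 1):
                for r in avoided_words(seq, k, -0.4, tree=tree, maws=maws):
                    union[r.word] = r.dev
            assert allres == union

    def test_longest_avoided_bounded_by_repeat_length(self):
        """No avoided word is longer than the longest repeated factor
        plus 2 (its infix must occur at least twice)."""
        rng = random.Random(9)
        for _ in range(20):
            x = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 300)))
            seq = Sequence("x", x)
            tree = build_suffix_tree(seq)
            res = all_avoided_words(seq, -1e-9, tree=tree)
            if res.records:
                lmax = max(len(w) for w in res.words())
                assert lmax <= longest_repeated_factor_length(tree) + 2

    def test_implicit_prefix_words_never_negative(self):
        """A word whose longest-proper-prefix locus is implicit satisfies
        f(w) = f(w_p) >= E(w), so its deviation is non-negative; such words
        can never enter a result set."""
        rng = random.Random(13)
        for _ in range(10):
            n = rng.randint(10, 80)
            x = "".join(rng.choice("ab") for _ in range(n))
            seq = Sequence("x", x)
            tree = build_suffix_tree(seq)
            for k in range(3, min(n + 1, 9)):
                for w, (f, E, d, *_r) in brute_force_dev_table(x, k).items():
                    if f == 0:
                        continue
                    loc = tree.locate(w[:-1])
                    if loc is not None and not loc.explicit:
                        assert d >= 0, (x, w)

    def test_maws_of_run_word_all_avoided_at_inverse_n(self):
        """For rho = -1/n every minimal absent word is avoided: its factors
        give E >= 1/n, hence dev <= -1/n."""
        seq = maw_rich_word(2, 12)
        maw_words = {t.word(seq) for t in compute_maws(seq)}
        res = all_avoided_words(seq, -1 / 12)
        absent = {r.word for r in res if r.status == ABSENT}
        assert absent == maw_words

    def test_result_count_bound(self):
        """|result| <= (sigma + 1) n - k + 1 for the fixed-length query."""
        rng = random.Random(21)
        for _ in range(20):
            n = rng.randint(5, 200)
            x = "".join(rng.choice("ACGT") for _ in range(n))
            seq = Sequence("x", x)
            tree = build_suffix_tree(seq)
            for k in (3, 5, 8):
                res = avoided_words(seq, k, -1e-9, tree=tree)
                assert len(res) <= (seq.sigma + 1) * n - k + 1

    def test_determinism(self, example_seq):
        a = avoided_words(example_seq, 3, -0.4)
        b = avoided_words(Sequence("example", str(example_seq.letters)), 3, -0.4)
        assert [(r.word, r.dev, r.status) for r in a] == [
            (r.word, r.dev, r.status) for r in b
        ]


def test_deviation_uses_unrounded_value(example_seq):
    """Threshold comparison happens before any 6-decimal formatting: a rho
    between the true dev and its rounded print must exclude the word."""
    res = avoided_words(example_seq, 3, -0.40824850)
    assert "CGT" not in res.words()  # true dev ~ -0.40824829 > rho
    res2 = avoided_words(example_seq, 3, -0.40824820)
    assert "CGT" in res2.words()
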