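"""Exact counting of strings with a fixed unique alphabet."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohsi.combinatorics import (
    ComponentInfo,
    ExactCountTable,
    count_closed_form,
    count_exact,
    count_subalphabet,
    enumerate_strings,
    het_information,
    het_information_asymptotic,
    system_info,
)


@pytest.mark.parametrize(
    "t, a, a_prime, expected",
    [
        (5, 2, 1, 2),  # AAAAA, BBBBB
        (5, 2, 2, 30),
        (5, 3, 3, 150),
        (5, 4, 4, 240),
        (5, 5, 5, 120),
        (4, 5, 5, 0),  # cannot use 5 distinct letters in 4 positions
        (3, 2, 2, 6),
        (6, 3, 3, 540),  # frozen from brute-force enumeration of 3**6 strings
    ],
)
def test_counts_agree_across_all_three_routes(t, a, a_prime, expected):
    """Recursion, inclusion-exclusion, and brute force give the same count."""
    assert count_subalphabet(t, a, a_prime) == expected
    if a_prime == a:
        assert count_exact(t, a) == expected
        assert count_closed_form(t, a) == expected
    alphabet = "ABCDE"[:a]
    n_enumerated = len(enumerate_strings(t, alphabet, a_prime)) * 1
    # enumerate_strings counts all a'-subsets of the alphabet at once
    assert n_enumerated == count_subalphabet(t, a, a_prime)


def test_oracle_equivalence_over_small_domain():
    for t in range(1, 11):
        for a in range(1, min(t, 5) + 1):
            n = count_exact(t, a)
            assert n == count_closed_form(t, a)
            assert n == len(enumerate_strings(t, "ABCDE"[:a], a))


def test_partition_identity_exact():
    """Sum over sub-alphabet usages of C(a,a') N(t,a';a') equals a**t."""
    for t in range(1, 21):
        for a in range(1, 9):
            total = sum(count_subalphabet(t, a, ap) for ap in range(1, a + 1))
            assert total == a**t


def test_bounding_and_factorial_identity():
    for a in range(2, 8):
        assert count_exact(a, a) == math.factorial(a)
        for t in range(a, a + 6):
            assert count_exact(t, a) < a**t


def test_worked_example_composition_terms():
    """The single-A and 3A/2B composition terms enumerate to 5 and 10."""
    strings = enumerate_strings(5, "AB", 2)
    assert len(strings) == 30
    assert "AAABB" in strings and "BBBAA" in strings
    assert sum(1 for s in strings if s.count("A") == 1) == 5
    assert sum(1 for s in strings if s.count("A") == 3) == 10
    assert enumerate_strings(5, "AB", 1) == ["AAAAA", "BBBBB"]
    assert enumerate_strings(2, "AB", 2) == ["AB", "BA"]


def test_het_information_values_and_bound():
    assert het_information(5, 2) == pytest.approx(math.log(30))
    assert het_information(5, 5) == pytest.approx(math.log(120))
    assert het_information(7, 1) == 0.0
    assert het_information_asymptotic(5, 2) == pytest.approx(math.log(32))
    assert het_information_asymptotic(1, 1) == 0.0
    # asymptotic form is an upper bound, equality only at a = 1
    for t, a in [(5, 2), (10, 3), (30, 7)]:
        assert het_information(t, a) < het_information_asymptotic(t, a)
    assert het_information(9, 1) == het_information_asymptotic(9, 1)


def test_het_information_handles_counts_beyond_float_range():
    # N(300, 22) is ~400 digits; the log must come off the big integer
    val = het_information(300, 22)
    assert val < het_information_asymptotic(300, 22) == pytest.approx(300 * math.log(22))
    assert val > 0.99 * 300 * math.log(22)


def test_het_information_strictly_increasing_in_t():
    for a in (1, 2, 4):
        vals = [het_information(t, a) for t in range(max(a, 2), 15)]
        assert all(v2 > v1 or a == 1 for v1, v2 in zip(vals, vals[1:]))


@pytest.mark.parametrize(
    "args", [(0, 2, 1), (5, 0, 1), (5, 2, 3), (5, 2, 0), (-1, 2, 1)]
)
def test_argument_errors(args):
    with pytest.raises((ValueError, TypeError)):
        count_subalphabet(*args)


def test_information_requires_a_at_most_t():
    with pytest.raises(ValueError):
        het_information(4, 5)


def test_system_info_totals_and_additivity():
    c52 = ComponentInfo.from_lengths(5, 2)
    c22 = ComponentInfo.from_lengths(2, 2)
    single = system_info([c52])
    assert single.total_info_I == pytest.approx(math.log(30))
    pair = system_info([c22, c22])
    assert pair.total_tokens_T == 4
    assert pair.log_omega == pytest.approx(math.log(6))  # 4!/(2!2!)
    a_part = system_info([c52, c22])
    b_part = system_info([c22])
    union = system_info([c52, c22, c22])
    assert union.total_info_I == pytest.approx(a_part.total_info_I + b_part.total_info_I)
    with pytest.raises(ValueError):
        system_info([])


@settings(deadline=None, max_examples=30)
@given(
    t=st.integers(min_value=1, max_value=25),
    a=st.integers(min_value=1, max_value=8),
)
def test_subalphabet_table_invariants(t, a):
    """Row invariants of the count table hold for arbitrary small (t, a)."""
    assert count_subalphabet(t, 1, 1) == 1
    for ap in range(1, a + 1):
        v = count_subalphabet(t, a, ap)
        assert v >= 0
        if ap > t:
            assert v == 0
    if a <= t:
        assert count_subalphabet(a, a, a) == math.factorial(a)


def test_exact_count_table_build_and_tsv_roundtrip(tmp_path):
    tab = ExactCountTable.build(6, 4)
    assert tab.values[(5, 2, 2)] == 30
    assert tab.values[(5, 3, 3)] == 150
    path = tmp_path / "counts.tsv"
    tab.to_tsv(path)
    back = ExactCountTable.from_tsv(path)
    assert back.values == tab.values
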