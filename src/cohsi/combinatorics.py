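"""Exact combinatorics of token strings with a fixed unique alphabet.

A *component* is an ordered string of ``t`` tokens drawn from an alphabet of
``a`` designated symbols, with the constraint that every one of the ``a``
symbols appears at least once.  The number of such strings, ``N(t, a)``, is a
surjection-type count; its natural logarithm is the Hartley–Shannon
information content of the component.  For ``t >> a`` the count approaches
``a**t`` and the information approaches ``t * log(a)``; the deficit at small
``t`` is what bends the predicted length distribution away from a pure power
law near the origin.

Everything here is exact integer arithmetic (Python big ints); floats appear
only when a logarithm is finally taken.  Two independent routes to the same
count are kept side by side — the recursion :func:`count_subalphabet` and the
inclusion–exclusion closed form :func:`count_closed_form` — so each serves as
a permanent regression oracle for the other.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

__all__ = [
    "ComponentInfo",
    "SystemInfo",
    "ExactCountTable",
    "count_subalphabet",
    "count_exact",
    "count_closed_form",
    "enumerate_strings",
    "het_information",
    "het_information_asymptotic",
    "system_info",
    "log_multinomial",
]

_ENUM_MAX_T = 12
_ENUM_MAX_STATES = 10**7


def _check_positive(name: str, value: int) -> None:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < 1:
        raise ValueError(f"{name} must be >= 1, got {value}")


@lru_cache(maxsize=None)
def _n_exact(t: int, a: int) -> int:
    """N(t, a; a): strings of length t over a designated letters using all a.

    Recursive form: a**t strings in total over the alphabet, minus those that
    use only a strict sub-alphabet, counted once per choice of sub-alphabet.
    """
    if a == 1:
        return 1
    total = a**t
    for k in range(1, a):
        total -= math.comb(a, k) * _n_exact(t, k)
    return total


def count_subalphabet(t: int, a: int, a_prime: int) -> int:
    """Number of length-``t`` strings over an ``a``-letter alphabet that use
    exactly ``a_prime`` distinct letters (any ``a_prime``-subset counts).

    Exact integer arithmetic throughout; returns 0 when ``a_prime > t``.
    """
    _check_positive("t", t)
    _check_positive("a", a)
    _check_positive("a_prime", a_prime)
    if a_prime > a:
        raise ValueError(f"a_prime={a_prime} exceeds alphabet size a={a}")
    if a_prime > t:
        return 0
    return math.comb(a, a_prime) * _n_exact(t, a_prime)


def count_exact(t: int, a: int) -> int:
    """N(t, a): length-``t`` strings over ``a`` letters using every letter."""
    _check_positive("t", t)
    _check_positive("a", a)
    if a > t:
        return 0
    return _n_exact(t, a)


def count_closed_form(t: int, a: int) -> int:
    """Inclusion–exclusion surjection count: sum_k (-1)^k C(a,k) (a-k)^t.

    Independent of the recursion; kept as a cross-validation oracle.
    """
    _check_positive("t", t)
    _check_positive("a", a)
    total = 0
    for k in range(a):
        term = math.comb(a, k) * (a - k) ** t
        total += -term if k % 2 else term
    return max(total, 0)


def enumerate_strings(
    t: int, alphabet: Sequence[str], exact_usage: int
) -> list[str]:
    """All length-``t`` strings over ``alphabet`` using exactly ``exact_usage``
    distinct tokens, lexicographically sorted.

    Brute force by construction (the ground-truth oracle for the counts);
    guarded to ``t <= 12`` and ``|alphabet|**t <= 1e7`` states.
    """
    _check_positive("t", t)
    _check_positive("exact_usage", exact_usage)
    letters = sorted(set(alphabet))
    if len(letters) != len(list(alphabet)):
        raise ValueError("alphabet contains duplicate tokens")
    if t > _ENUM_MAX_T or len(letters) ** t > _ENUM_MAX_STATES:
        raise ValueError(
            f"enumeration guard exceeded: t={t}, |alphabet|={len(letters)}"
        )
    if exact_usage > len(letters):
        raise ValueError("exact_usage exceeds alphabet size")
    out = [
        "".join(s)
        for s in itertools.product(letters, repeat=t)
        if len(set(s)) == exact_usage
    ]
    return out


def het_information(t: int, a: int) -> float:
    """Hartley–Shannon information log N(t, a) in nats.

    The log is taken on the big integer directly, so counts far beyond float
    range are handled without overflow.
    """
    _check_positive("t", t)
    _check_positive("a", a)
    if a > t:
        raise ValueError(f"a={a} > t={t}: no string can use more letters than positions")
    return math.log(count_exact(t, a))


def het_information_asymptotic(t: int, a: int) -> float:
    """Asymptotic information ``t * log(a)`` (valid for t >> a).

    Always an upper bound on :func:`het_information`; equality only at a = 1.
    """
    _check_positive("t", t)
    _check_positive("a", a)
    return t * math.log(a)


def log_multinomial(lengths: Iterable[int]) -> float:
    """Exact log(T! / prod t_i!) for the microstate multiplicity of a system."""
    ts = list(lengths)
    total = math.factorial(sum(ts))
    for t in ts:
        total //= math.factorial(t)
    return math.log(total)


@dataclass(frozen=True)
class ComponentInfo:
    """One component: length ``t``, unique alphabet ``a``, information in nats."""

    length_t: int
    alphabet_a: int
    info_nats: float

    def __post_init__(self) -> None:
        if not 1 <= self.alphabet_a <= self.length_t:
            raise ValueError(
                f"need 1 <= a <= t, got a={self.alphabet_a}, t={self.length_t}"
            )
        if self.info_nats > self.length_t * math.log(max(self.alphabet_a, 1)) + 1e-9:
            raise ValueError("info_nats exceeds the t*log(a) upper bound")

    @classmethod
    def from_lengths(cls, t: int, a: int) -> "ComponentInfo":
        return cls(t, a, het_information(t, a))


@dataclass(frozen=True)
class SystemInfo:
    """System totals: tokens T, components M, information I, log multiplicity."""

    total_tokens_T: int
    n_components_M: int
    total_info_I: float
    log_omega: float


def system_info(components: Sequence[ComponentInfo]) -> SystemInfo:
    """Aggregate totals for a heterogeneous system.

    Information is additive over components; the multiplicity log_omega is the
    exact multinomial log(T!/prod t_i!), the number of ways of distributing
    the T tokens over the component slots.
    """
    if not components:
        raise ValueError("system must contain at least one component")
    lengths = [c.length_t for c in components]
    return SystemInfo(
        total_tokens_T=sum(lengths),
        n_components_M=len(components),
        total_info_I=float(sum(c.info_nats for c in components)),
        log_omega=log_multinomial(lengths),
    )


@dataclass
class ExactCountTable:
    """Tabulated N(t, a; a') values with exact integers.

    Serializable as TSV with the count rendered as a decimal string, so
    arbitrary precision survives the round trip.
    """

    max_t: int
    max_a: int
    values: dict[tuple[int, int, int], int] = field(default_factory=dict)

    @classmethod
    def build(cls, max_t: int, max_a: int) -> "ExactCountTable":
        _check_positive("max_t", max_t)
        _check_positive("max_a", max_a)
        tab = cls(max_t=max_t, max_a=max_a)
        for t in range(1, max_t + 1):
            for a in range(1, max_a + 1):
                for ap in range(1, a + 1):
                    tab.values[(t, a, ap)] = count_subalphabet(t, a, ap)
        return tab

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("t\ta\ta_prime\tcount\n")
            for (t, a, ap), v in sorted(self.values.items()):
                fh.write(f"{t}\t{a}\t{ap}\t{v}\n")

    @classmethod
    def from_tsv(cls, path) -> "ExactCountTable":
        values: dict[tuple[int, int, int], int] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["t", "a", "a_prime", "count"]:
                raise ValueError(f"unexpected header {header!r}")
            for line in fh:
                ts, as_, aps, vs = line.rstrip("\n").split("\t")
                values[(int(ts), int(as_), int(aps))] = int(vs)
        max_t = max(k[0] for k in values)
        max_a = max(k[1] for k in values)
        return cls(max_t=max_t, max_a=max_a, values=values)
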