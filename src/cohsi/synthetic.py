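"""Seeded generators producing desk-scale inputs with known ground truth.

Every pipeline stage gets an input whose true parameters are known by
construction: uniform draws over the exactly-counted admissible strings,
discrete power-law length samples for calibrating the tail fitter, Zipf rank
tables, note-event corpora whose two alphabets obey a prescribed power-law
relation, and exhaustive microstate enumerations of tiny systems that verify
the statistical-mechanics premise (the modal macrostate is the one with the
most microstates) by brute force.

All randomness flows through one explicit numpy Generator; a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .combinatorics import het_information
from .systems_io import DURATION_CLASSES, MAX_PITCH
from .tailfit import sample_discrete_powerlaw

__all__ = [
    "sample_exact_alphabet_string",
    "generate_powerlaw_lengths",
    "generate_zipf_bins",
    "generate_dual_alphabet_corpus",
    "enumerate_microstates",
    "write_fasta",
]

_DEFAULT_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_exact_alphabet_string(
    t: int, a: int, seed=0, alphabet: str = _DEFAULT_ALPHABET
) -> str:
    """Uniform draw over the N(t, a) strings of length t using exactly the
    first ``a`` letters of ``alphabet`` (each at least once).

    Rejection sampling from the a**t unconstrained strings; the acceptance
    probability N(t, a)/a**t is bounded away from zero for t >= a, so
    termination is guaranteed.
    """
    if a > t:
        raise ValueError(f"a={a} > t={t}: no admissible string")
    if a < 1:
        raise ValueError("a must be >= 1")
    if a > len(alphabet):
        raise ValueError("alphabet too small")
    rng = _rng(seed)
    letters = alphabet[:a]
    while True:
        idx = rng.integers(0, a, size=t)
        if len(set(idx.tolist())) == a:
            return "".join(letters[i] for i in idx)


def generate_powerlaw_lengths(exponent: float, xmin: int, n: int, seed=0) -> np.ndarray:
    """i.i.d. discrete power-law sample (pdf exponent ``exponent``, support
    x >= xmin) via exact inverse transform on the zeta normalisation."""
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return sample_discrete_powerlaw(exponent, int(xmin), int(n), _rng(seed))


def generate_zipf_bins(eta: float, t1: float, M: int) -> np.ndarray:
    """Deterministic Zipf rank table: t_i = round(t1 * i**-eta), floored at 1."""
    ranks = np.arange(1, M + 1, dtype=float)
    return np.maximum(np.rint(t1 * ranks**-eta), 1).astype(int)


def generate_dual_alphabet_corpus(
    gamma: float,
    c: float = 1.0,
    n_comps: int = 100,
    noise_sd: float = 0.0,
    seed=0,
    a_prime_range: tuple[int, int] = (5, 45),
) -> pd.DataFrame:
    """Note-event corpus whose alphabets satisfy a'' ~= c * a'**gamma.

    For each composition a pitch alphabet size a' is drawn uniformly from
    ``a_prime_range``, the target duration alphabet a'' = c * a'**gamma gets
    multiplicative log-normal noise of scale ``noise_sd`` and is clipped to
    the feasible band [a', 7a']; events are then constructed so the realised
    alphabets match the targets exactly (verified post hoc).
    """
    if n_comps < 2:
        raise ValueError("need at least 2 compositions")
    rng = _rng(seed)
    lo, hi = a_prime_range
    if not 1 <= lo <= hi <= MAX_PITCH:
        raise ValueError(f"a_prime_range must lie within 1..{MAX_PITCH}")
    rows = []
    for j in range(n_comps):
        a_prime = int(rng.integers(lo, hi + 1))
        target = c * a_prime**gamma
        if noise_sd > 0:
            target *= math.exp(rng.normal(0.0, noise_sd))
        a_dd = int(np.clip(round(target), a_prime, 7 * a_prime))
        pitches = rng.choice(MAX_PITCH, size=a_prime, replace=False) + 1
        # distribute the a'' - a' extra (pitch, duration) pairs: each pitch
        # starts with one duration and can take up to 6 more
        extra = np.zeros(a_prime, dtype=int)
        remaining = a_dd - a_prime
        order = rng.permutation(a_prime)
        for p in itertools.cycle(order):
            if remaining == 0:
                break
            if extra[p] < len(DURATION_CLASSES) - 1:
                extra[p] += 1
                remaining -= 1
        comp_id = f"comp{j:04d}"
        for p_idx, pitch in enumerate(pitches):
            n_dur = 1 + extra[p_idx]
            durs = rng.choice(len(DURATION_CLASSES), size=n_dur, replace=False)
            for d in durs:
                rows.append((comp_id, int(pitch), DURATION_CLASSES[d]))
    events = pd.DataFrame(rows, columns=["composition_id", "pitch", "duration_class"])
    _verify_dual_corpus(events)
    return events


def _verify_dual_corpus(events: pd.DataFrame) -> None:
    for _, grp in events.groupby("composition_id"):
        a_p = grp["pitch"].nunique()
        a_dd = len(set(zip(grp["pitch"], grp["duration_class"])))
        if not a_p <= a_dd <= 7 * a_p:
            raise RuntimeError("generation error: realised alphabets out of band")


def enumerate_microstates(
    T: int, M: int, alphabets: Sequence[int]
) -> pd.DataFrame:
    """Exhaustive macrostate table for a tiny heterogeneous system.

    Enumerates every composition (t_1..t_M) with sum t_i = T and t_i >= a_i,
    recording the exact multinomial multiplicity T!/prod(t_i!) and the total
    information sum_i log N(t_i, a_i).  The row with the largest multiplicity
    is the modal macrostate the variational argument singles out.
    Guarded to T <= 12, M <= 3.
    """
    if T > 12 or M > 3:
        raise ValueError("enumeration guard: T <= 12 and M <= 3")
    if len(alphabets) != M:
        raise ValueError("alphabets must have length M")
    if sum(alphabets) > T:
        raise ValueError("no composition satisfies t_i >= a_i")
    rows = []
    for parts in _compositions(T, M):
        if any(t < a for t, a in zip(parts, alphabets)):
            continue
        mult = math.factorial(T)
        for t in parts:
            mult //= math.factorial(t)
        info = sum(het_information(t, a) for t, a in zip(parts, alphabets))
        rows.append((parts, mult, info))
    df = pd.DataFrame(rows, columns=["composition", "multiplicity", "total_info"])
    df["modal"] = df["multiplicity"] == df["multiplicity"].max()
    return df


def _compositions(T: int, M: int):
    if M == 1:
        yield (T,)
        return
    for first in range(1, T - M + 2):
        for rest in _compositions(T - first, M - 1):
            yield (first, *rest)


def write_fasta(table_or_lengths, path, seed=0) -> None:
    """Write a synthetic FASTA file with one record per (t, a) pair.

    Accepts a sequence of (t, a) tuples; each record is a uniform draw over
    the admissible strings for that pair.
    """
    rng = _rng(seed)
    with open(path, "w", encoding="utf-8") as fh:
        for i, (t, a) in enumerate(table_or_lengths):
            seq = sample_exact_alphabet_string(int(t), int(a), rng)
            fh.write(f">synthetic_{i:05d} t={t} a={a}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
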