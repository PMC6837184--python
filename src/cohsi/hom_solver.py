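"""Homogeneous systems: Zipf's law in rank with a drooping tail.

A homogeneous system is a set of M bins, bin i holding t_i identical tokens
of a kind unique to that bin, in no distinguishable order.  The number of
ways of assembling such a system is N_h = T! * prod_i (1/i)**t_i, giving an
information content log T! - sum_i t_i log i.  Maximising the microstate
count at fixed size and information (multipliers kappa and eta) leads to the
stationarity condition, per occupied rank i:

    d/dt [log t!] = -kappa - eta * log i

Under Stirling's approximation d/dt[log t!] ~= log t this is exactly Zipf's
law, t_i = exp(-kappa - eta log i) ~ i**-eta.  Keeping more of the log
factorial — Ramanujan's refinement, or the exact derivative psi(t+1) (the
digamma function) — raises the left side for small t, so sparsely populated
high ranks fall *below* the Zipf line: the droop in the tail emerges from the
arithmetic alone, with the ordering exact <= ramanujan <= stirling at every
rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

__all__ = [
    "LagrangeParamsHom",
    "RankSolution",
    "hom_information",
    "solve_hom",
    "droop_profile",
    "inverse_digamma",
]

Approximation = Literal["stirling", "ramanujan", "exact"]

# psi(1) = -Euler-Mascheroni: targets below this admit no t >= 0
_PSI_1 = float(digamma(1.0))


@dataclass(frozen=True)
class LagrangeParamsHom:
    """Multipliers for the homogeneous equation; eta is the Zipf exponent."""

    kappa: float
    eta: float
    approximation: Approximation = "stirling"

    def __post_init__(self) -> None:
        if not math.isfinite(self.eta) or not math.isfinite(self.kappa):
            raise ValueError("kappa and eta must be finite")
        if self.approximation not in ("stirling", "ramanujan", "exact"):
            raise ValueError(f"unknown approximation {self.approximation!r}")


@dataclass
class RankSolution:
    """Bin populations by rank (rank 1 = most populated, Zipf convention)."""

    ranks: np.ndarray  # 1..M
    counts: np.ndarray  # t_i per rank; NaN where the rank is unpopulated
    params: LagrangeParamsHom

    @property
    def populated(self) -> np.ndarray:
        return ~np.isnan(self.counts)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tcount\n")
            for r, c in zip(self.ranks, self.counts):
                fh.write(f"{r}\t{c:.17g}\n")


def hom_information(counts: Sequence[int]) -> float:
    """Information content log T! - sum_i t_i log i of a homogeneous system.

    Bins are ranked internally by descending population (rank 1 = largest),
    so the result is invariant to the input order; log T! is computed exactly
    on the big integer.
    """
    ts = sorted(int(c) for c in counts)
    if not ts:
        raise ValueError("counts must be nonempty")
    if any(t <= 0 for t in ts):
        raise ValueError("counts must be positive integers")
    ts.reverse()  # descending: largest bin gets rank 1 (log 1 = 0)
    T = sum(ts)
    total = math.log(math.factorial(T))
    for i, t in enumerate(ts, start=1):
        total -= t * math.log(i)
    return total


def _ramanujan_dlogfact(t: float) -> float:
    """Derivative of Ramanujan's log-factorial approximation.

    log t! ~= t log t - t + (1/6) log(8t^3 + 4t^2 + t + 1/30) + (1/2) log pi;
    term-wise differentiation gives log t + (24t^2 + 8t + 1) / (6 (8t^3 +
    4t^2 + t + 1/30)).
    """
    return math.log(t) + (24 * t * t + 8 * t + 1) / (
        6 * (8 * t**3 + 4 * t * t + t + 1 / 30)
    )


def inverse_digamma(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi(x) = y for x > 0 by guarded Newton iteration.

    Start from the asymptotic inverse exp(y) + 1/2 (good for y >> 0) or the
    near-pole form -1/(y - psi(1)) region fallback, then Newton with the
    trigamma derivative, halving steps that leave the domain.
    """
    if y >= -2.22:
        x = math.exp(y) + 0.5
    else:
        x = -1.0 / (y - _PSI_1)
    for _ in range(max_iter):
        fx = float(digamma(x)) - y
        if abs(fx) < tol:
            return x
        step = fx / float(polygamma(1, x))
        x_new = x - step
        while x_new <= 0:
            step /= 2.0
            x_new = x - step
        x = x_new
    raise RuntimeError(f"digamma inversion failed to converge for y={y}")


def solve_hom(params: LagrangeParamsHom, M: int) -> RankSolution:
    """Bin populations t_i for ranks 1..M under the chosen log-factorial
    treatment.

    stirling:  t_i = exp(-kappa - eta log i) in closed form (pure Zipf).
    ramanujan: root of the Ramanujan-derivative condition, bracketed + Brent.
    exact:     t_i = psi^{-1}(-kappa - eta log i) - 1 via Newton inversion of
               the digamma function, to |psi(t+1) - target| < 1e-10.

    Ranks whose target falls below psi(1) (no nonnegative population solves
    the condition) are reported as unpopulated (NaN), not as an error.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    ranks = np.arange(1, M + 1)
    targets = -params.kappa - params.eta * np.log(ranks)
    counts = np.empty(M, dtype=float)
    for j, y in enumerate(targets):
        if params.approximation == "stirling":
            counts[j] = math.exp(y)
        elif params.approximation == "exact":
            if y < _PSI_1:
                counts[j] = np.nan
                continue
            counts[j] = inverse_digamma(float(y)) - 1.0
        else:  # ramanujan
            counts[j] = _solve_ramanujan(float(y))
    return RankSolution(ranks=ranks, counts=counts, params=params)


def _solve_ramanujan(y: float) -> float:
    # derivative is increasing; bracket by doubling/halving around exp(y)
    lo = hi = max(math.exp(y), 1e-9)
    while _ramanujan_dlogfact(hi) < y:
        hi *= 2.0
    while _ramanujan_dlogfact(lo) > y:
        lo /= 2.0
        if lo < 1e-12:
            return np.nan  # target below the derivative's infimum on (0, inf)
    return float(brentq(lambda t: _ramanujan_dlogfact(t) - y, lo, hi, xtol=1e-12))


def droop_profile(
    sol_exact: RankSolution, sol_stirling: RankSolution
) -> list[tuple[int, float]]:
    """(rank, t_exact / t_stirling) per populated rank.

    The ratio lives in (0, 1] and shrinks as bins get sparser: the droop.
    """
    pe, ps = sol_exact.params, sol_stirling.params
    if (pe.kappa, pe.eta) != (ps.kappa, ps.eta) or len(sol_exact.ranks) != len(
        sol_stirling.ranks
    ):
        raise ValueError("solutions must share (kappa, eta, M)")
    out = []
    for r, te, tstir in zip(sol_exact.ranks, sol_exact.counts, sol_stirling.counts):
        if np.isnan(te) or np.isnan(tstir):
            continue
        out.append((int(r), float(te / tstir)))
    return out
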