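"""Solver for the heterogeneous implicit length equation.

The constrained maximisation of the microstate count of a heterogeneous
system (total tokens T and total Hartley–Shannon information I held fixed by
Lagrange multipliers alpha and beta) yields the implicit condition

    log t + alpha + beta * dI/dt = 0,        I(t, a) = log N(t, a),

whose root locus in the (t, a) plane is the predicted length distribution.
For t >> a the derivative dI/dt tends to log a and the condition collapses to
the explicit pure power law t = exp(-alpha - beta * log a), i.e. t ~ a**-beta.
Because dI/dt approaches log a strictly from above (for a >= 2), the full
locus sits on one side of the power law, converging onto it as t/a grows —
the region between the two is exactly the departure that creates the unimodal
peak near the origin.

Sign convention: with the condition written literally, physically admissible
roots (t >= a >= 1) require exp(-alpha) to be large, i.e. alpha negative for
beta > 0.  ``as_printed`` takes (alpha, beta) literally; ``reflected`` negates
both, so positive parameter pairs quoted for illustrative solutions produce
the same admissible locus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import brentq

from .infogrid import InfoGrid, continue_real

__all__ = [
    "LagrangeParamsHet",
    "SolutionLocus",
    "residual",
    "solve_locus",
    "pure_power_locus",
    "departure_profile",
]

_RESIDUAL_TOL = 1e-6


@dataclass(frozen=True)
class LagrangeParamsHet:
    """Multipliers for the heterogeneous equation.

    alpha scales the total-size constraint, beta the total-information
    constraint; beta sets the asymptotic power-law exponent t ~ a**-beta.
    """

    alpha: float
    beta: float
    sign_convention: Literal["as_printed", "reflected"] = "as_printed"

    def __post_init__(self) -> None:
        if self.beta == 0:
            raise ValueError("beta must be nonzero")
        if self.sign_convention not in ("as_printed", "reflected"):
            raise ValueError(f"unknown sign_convention {self.sign_convention!r}")

    @property
    def effective(self) -> tuple[float, float]:
        """(alpha, beta) after applying the sign convention."""
        if self.sign_convention == "reflected":
            return -self.alpha, -self.beta
        return self.alpha, self.beta


@dataclass
class SolutionLocus:
    """Roots (t, a) of the implicit equation, one or more per alphabet line."""

    points: list[tuple[float, float]] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    mode: str = "t_of_a"

    def t_for_a(self, a: float) -> float:
        """Primary (smallest-t) root on the a-line; KeyError if none."""
        ts = [t for t, aa in self.points if aa == a]
        if not ts:
            raise KeyError(f"no root recorded for a={a}")
        return min(ts)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("a\tt\tresidual\n")
            for (t, a), r in zip(self.points, self.residuals):
                fh.write(f"{a:.17g}\t{t:.17g}\t{r:.17g}\n")


def residual(
    t: float, a: float, params: LagrangeParamsHet, grid: InfoGrid
) -> float:
    """log t + alpha + beta * dI/dt at (t, a), under the sign convention."""
    alpha, beta = params.effective
    a_int = int(round(a))
    if a_int != a:
        raise ValueError("alphabet a must be an integer grid line")
    _, didt = continue_real(grid, t, a_int)
    return math.log(t) + alpha + beta * didt


def solve_locus(
    params: LagrangeParamsHet,
    grid: InfoGrid,
    mode: str = "t_of_a",
    a_range: Iterable[int] | None = None,
) -> SolutionLocus:
    """Root locus of the implicit equation over the grid.

    For each alphabet line the residual is scanned on the integer nodes;
    every sign change is bracketed and refined by bisection (Brent) to
    |residual| < 1e-6.  Lines with no sign change contribute no point — the
    smallest lengths genuinely may admit no solution — and an entirely empty
    locus triggers a warning rather than an error.
    """
    if mode != "t_of_a":
        raise ValueError("only mode='t_of_a' is implemented")
    if a_range is None:
        a_range = range(1, grid.a_max + 1)
    locus = SolutionLocus(mode=mode)
    for a in a_range:
        roots = _roots_on_line(params, grid, int(a))
        for t_root in roots:
            locus.points.append((t_root, float(a)))
            locus.residuals.append(residual(t_root, a, params, grid))
    if not locus.points:
        warnings.warn(
            "no roots of the implicit equation on this grid for these "
            "multipliers; the locus is empty",
            stacklevel=2,
        )
    return locus


def _roots_on_line(params: LagrangeParamsHet, grid: InfoGrid, a: int) -> list[float]:
    ts = np.arange(a, grid.t_max + 1)
    res = np.array([residual(float(t), a, params, grid) for t in ts])
    roots: list[float] = []
    for i in range(len(ts) - 1):
        r0, r1 = res[i], res[i + 1]
        if r0 == 0.0:
            roots.append(float(ts[i]))
        elif r0 * r1 < 0:
            root = brentq(
                lambda t: residual(t, a, params, grid),
                float(ts[i]),
                float(ts[i + 1]),
                xtol=1e-12,
            )
            roots.append(float(root))
    if len(res) and res[-1] == 0.0:
        roots.append(float(ts[-1]))
    # refine guarantee: every root must meet the residual tolerance
    return [r for r in roots if abs(residual(r, a, params, grid)) < _RESIDUAL_TOL]


def pure_power_locus(
    params: LagrangeParamsHet, a_range: Iterable[int]
) -> SolutionLocus:
    """Asymptotic pure power law t(a) = exp(-alpha - beta log a)."""
    alpha, beta = params.effective
    locus = SolutionLocus(mode="t_of_a")
    for a in a_range:
        t = math.exp(-alpha - beta * math.log(a))
        locus.points.append((t, float(a)))
        locus.residuals.append(0.0)
    return locus


def departure_profile(
    full: SolutionLocus, pure: SolutionLocus
) -> list[tuple[float, float, float]]:
    """Per-alphabet gap (a, t_full, t_full - t_pure) on the shared a-range.

    The gap is one-signed (dI/dt >= log a pushes the full root below the pure
    one wherever the deficit is active) and vanishes as t/a grows.
    """
    full_a = {a for _, a in full.points}
    pure_a = {a for _, a in pure.points}
    shared = sorted(full_a & pure_a)
    if not shared:
        raise ValueError("loci share no alphabet lines")
    out = []
    for a in shared:
        tf = full.t_for_a(a)
        tp = pure.t_for_a(a)
        out.append((a, tf, tf - tp))
    return out
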