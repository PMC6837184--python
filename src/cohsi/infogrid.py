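"""Real-valued continuation of log N(t, a) and its length-derivative.

The implicit heterogeneous length equation needs ``dI/dt`` at arbitrary real
``t``, but the exact count N(t, a) lives on integer nodes.  The grid stores
exact big-integer logs at every integer node ``a <= t <= t_max`` and a
second-order finite-difference derivative on the unit spacing; a
monotone-preserving piecewise-cubic (PCHIP) interpolant per alphabet line
supplies values between nodes, coinciding with the exact values at the nodes
themselves.

For ``a >= 2`` the derivative approaches ``log a`` from above as ``t`` grows:
the information deficit relative to ``t log a`` shrinks, which is the source
of the unimodal departure from the pure power law near the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["InfoGrid", "build_grid", "continue_real"]

_DEFAULT_T_MAX = 200
_DEFAULT_A_MAX = 30
_T_MAX_GUARD = 500


@dataclass
class InfoGrid:
    """log N(t, a) and d log N/dt on the integer grid, NaN where t < a."""

    t_values: np.ndarray  # shape (t_max,), 1..t_max
    a_values: np.ndarray  # shape (a_max,), 1..a_max
    logN: np.ndarray  # shape (t_max, a_max); NaN for t < a
    dlogN_dt: np.ndarray  # same shape
    _interp: dict = field(default_factory=dict, repr=False)

    @property
    def t_max(self) -> int:
        return int(self.t_values[-1])

    @property
    def a_max(self) -> int:
        return int(self.a_values[-1])

    def _interpolators(self, a: int):
        """(logN, dlogN_dt) PCHIP interpolants along the a-th alphabet line."""
        if a not in self._interp:
            tt = np.arange(a, self.t_max + 1)
            col = a - 1
            f = self.logN[a - 1 :, col]
            g = self.dlogN_dt[a - 1 :, col]
            if len(tt) < 2:
                raise ValueError(f"alphabet line a={a} has fewer than 2 nodes")
            self._interp[a] = (
                PchipInterpolator(tt, f, extrapolate=False),
                PchipInterpolator(tt, g, extrapolate=False),
            )
        return self._interp[a]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("t\ta\tlogN\tdlogN_dt\n")
            for ai, a in enumerate(self.a_values):
                for ti, t in enumerate(self.t_values):
                    if t < a:
                        continue
                    fh.write(
                        f"{t}\t{a}\t{self.logN[ti, ai]:.17g}\t{self.dlogN_dt[ti, ai]:.17g}\n"
                    )

    @classmethod
    def from_tsv(cls, path) -> "InfoGrid":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["t", "a", "logN", "dlogN_dt"]:
                raise ValueError(f"unexpected header {header!r}")
            for line in fh:
                t, a, f, g = line.rstrip("\n").split("\t")
                rows.append((int(t), int(a), float(f), float(g)))
        t_max = max(r[0] for r in rows)
        a_max = max(r[1] for r in rows)
        logN = np.full((t_max, a_max), np.nan)
        dlogN = np.full((t_max, a_max), np.nan)
        for t, a, f, g in rows:
            logN[t - 1, a - 1] = f
            dlogN[t - 1, a - 1] = g
        return cls(
            t_values=np.arange(1, t_max + 1),
            a_values=np.arange(1, a_max + 1),
            logN=logN,
            dlogN_dt=dlogN,
        )


def build_grid(t_max: int = _DEFAULT_T_MAX, a_max: int = _DEFAULT_A_MAX) -> InfoGrid:
    """Exact log N at integer nodes plus finite-difference dlogN/dt.

    Counts are evaluated with the inclusion–exclusion closed form in exact
    integer arithmetic (no cancellation once integers are exact) and logged as
    big integers.  Derivatives: second-order central differences on the unit
    t-spacing, with one-sided second-order stencils at the t = a boundary and
    at t_max.
    """
    if a_max > t_max:
        raise ValueError(f"a_max={a_max} must not exceed t_max={t_max}")
    if t_max > _T_MAX_GUARD:
        raise ValueError(f"t_max={t_max} exceeds guard {_T_MAX_GUARD}")
    logN = np.full((t_max, a_max), np.nan)
    for a in range(1, a_max + 1):
        # incremental powers (a-k)^t avoid recomputing big pows from scratch
        signs = [(-1) ** k * math.comb(a, k) for k in range(a)]
        powers = [1] * a  # (a-k)^0
        for t in range(1, t_max + 1):
            for k in range(a):
                powers[k] *= a - k
            if t < a:
                continue
            n = sum(s * p for s, p in zip(signs, powers))
            logN[t - 1, a - 1] = math.log(n) if n > 0 else np.nan
    dlogN = np.full((t_max, a_max), np.nan)
    for a in range(1, a_max + 1):
        col = a - 1
        f = logN[a - 1 :, col]
        g = np.empty_like(f)
        if len(f) >= 3:
            g[1:-1] = (f[2:] - f[:-2]) / 2.0
            g[0] = (-3 * f[0] + 4 * f[1] - f[2]) / 2.0
            g[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / 2.0
        elif len(f) == 2:
            g[:] = f[1] - f[0]
        else:
            g[:] = 0.0
        dlogN[a - 1 :, col] = g
    # a = 1 line: N(t,1) = 1 identically, derivative exactly zero
    dlogN[:, 0] = 0.0
    return InfoGrid(
        t_values=np.arange(1, t_max + 1),
        a_values=np.arange(1, a_max + 1),
        logN=logN,
        dlogN_dt=dlogN,
    )


def continue_real(grid: InfoGrid, t: float, a: int) -> tuple[float, float]:
    """(log N, d log N/dt) at real ``t`` on the integer-``a`` line.

    Exact (to the float) at integer nodes; monotone between them.
    """
    if not 1 <= a <= grid.a_max:
        raise ValueError(f"a={a} outside grid alphabet range 1..{grid.a_max}")
    if t < a or t > grid.t_max:
        raise ValueError(f"t={t} outside the domain [{a}, {grid.t_max}] for a={a}")
    if float(t).is_integer():
        ti = int(t) - 1
        return float(grid.logN[ti, a - 1]), float(grid.dlogN_dt[ti, a - 1])
    f_int, g_int = grid._interpolators(a)
    return float(f_int(t)), float(g_int(t))
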