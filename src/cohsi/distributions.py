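"""Empirical distribution machinery for component tables.

Covers the descriptive layer of the analysis: complementary cumulative
distribution functions (the noise-reduced view in which a power-law tail is a
straight line on log-log axes), geometric ("exponential") binning that
balances bin contents under heavy tails, recategorisation of a length sample
into a homogeneous rank/frequency table, and the dual-alphabet pairing used
to test the predicted power-law relation between two consistent alphabets of
the same system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CCDF",
    "BinnedTail",
    "ccdf",
    "exponential_bin",
    "rank_recategorize",
    "dual_alphabet_table",
]


@dataclass
class CCDF:
    """P(X >= x) at each distinct observed value (>= convention)."""

    x: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        if self.p[0] != 1.0 or np.any(np.diff(self.p) > 0) or np.any(self.p <= 0):
            raise ValueError("invalid ccdf: must start at 1, be nonincreasing, positive")


def ccdf(values) -> CCDF:
    """Empirical ccdf P(X >= x) of a positive integer sample."""
    v = np.asarray(values)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    x = np.unique(v)
    # #{v >= x}: rank of x in the sorted sample from the top
    counts_ge = v.size - np.searchsorted(np.sort(v), x, side="left")
    return CCDF(x=x.astype(float), p=counts_ge / v.size)


@dataclass
class BinnedTail:
    """Geometric bins: edges, per-bin counts, and width-normalised density."""

    edges: np.ndarray  # length K+1, strictly increasing geometric progression
    counts: np.ndarray  # length K
    density: np.ndarray  # counts / width

    @property
    def midpoints(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])  # geometric midpoints


def exponential_bin(values, ratio: float, x_low: float) -> BinnedTail:
    """Bin the tail ``values >= x_low`` into geometric bins x_low * ratio**k.

    Bins are half-open [e_k, e_{k+1}) except the last, which is closed so the
    maximum is covered.  Density is count divided by bin width, the quantity
    that stays linear on log-log axes under a power law.
    """
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    v = np.asarray(values, dtype=float)
    v = v[v >= x_low]
    if v.size == 0:
        raise ValueError(f"no values at or above x_low={x_low}")
    edges = [float(x_low)]
    vmax = v.max()
    while edges[-1] < vmax:
        edges.append(edges[-1] * ratio)
    if len(edges) == 1:  # all values equal x_low
        edges.append(edges[0] * ratio)
    edges = np.array(edges)
    counts, _ = np.histogram(v, bins=edges)  # numpy closes the final bin
    widths = np.diff(edges)
    return BinnedTail(edges=edges, counts=counts, density=counts / widths)


def rank_recategorize(table: pd.DataFrame, column: str = "length") -> pd.DataFrame:
    """Recast a heterogeneous length sample as a homogeneous rank table.

    Each distinct length becomes a bin; its frequency is the number of
    components of that length.  Bins are ranked by descending frequency,
    ties broken by ascending length, ranks 1..K.  Component count is
    conserved exactly.
    """
    if len(table) == 0:
        raise ValueError("component table is empty")
    freq = (
        table.groupby(column).size().reset_index(name="frequency")
    )
    freq = freq.sort_values(
        ["frequency", column], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(freq) + 1),
            "frequency": freq["frequency"].to_numpy(),
            "representative_value": freq[column].to_numpy(),
        }
    )
    assert out["frequency"].sum() == len(table)
    return out


def dual_alphabet_table(notes: pd.DataFrame) -> pd.DataFrame:
    """Per-composition pairing of the two alphabets of the same events.

    a_prime counts distinct pitches; a_doubleprime counts distinct
    (pitch, duration_class) pairs.  The downstream test regresses
    log(a_doubleprime) on log(a_prime): under the theory the two consistent
    categorisations are related as a power law.
    """
    from .systems_io import components_from_notes

    no_dur = components_from_notes(notes, with_duration=False)
    with_dur = components_from_notes(notes, with_duration=True)
    if len(no_dur) < 2:
        raise ValueError("need at least 2 compositions for the dual-alphabet table")
    merged = pd.DataFrame(
        {
            "composition_id": no_dur["component_id"],
            "a_prime": no_dur["alphabet"].to_numpy(),
            "a_doubleprime": with_dur["alphabet"].to_numpy(),
        }
    )
    bad = merged[
        (merged["a_doubleprime"] < merged["a_prime"])
        | (merged["a_doubleprime"] > 7 * merged["a_prime"])
    ]
    if len(bad):
        raise AssertionError(f"alphabet bound a' <= a'' <= 7a' violated: {bad}")
    return merged
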