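"""Root locus of the heterogeneous implicit length equation."""

import math

import numpy as np
import pytest

from cohsi.het_solver import (
    LagrangeParamsHet,
    departure_profile,
    pure_power_locus,
    residual,
    solve_locus,
)


def test_residual_on_single_letter_line(default_grid):
    """dI/dt = 0 for a = 1, so the residual reduces to log t + alpha."""
    p = LagrangeParamsHet(alpha=0.0, beta=3.7)
    assert residual(10.0, 1.0, p, default_grid) == pytest.approx(math.log(10.0))


def test_residual_asymptotic_zero(tall_grid):
    """Near t = e^6/2 with (alpha=-6, beta=1), a=2 the residual vanishes."""
    p = LagrangeParamsHet(alpha=-6.0, beta=1.0)
    assert residual(math.exp(6) / 2, 2.0, p, tall_grid) == pytest.approx(0.0, abs=1e-3)


def test_reflected_convention_negates_both_multipliers():
    p = LagrangeParamsHet(6.0, 0.5, "reflected")
    assert p.effective == (-6.0, -0.5)
    assert LagrangeParamsHet(6.0, 0.5).effective == (6.0, 0.5)
    with pytest.raises(ValueError):
        LagrangeParamsHet(1.0, 0.0)


def test_as_printed_positive_multipliers_have_no_admissible_roots(default_grid):
    """Literal positive (6, 0.5) pushes all roots below t = 1: empty locus."""
    with pytest.warns(UserWarning):
        locus = solve_locus(LagrangeParamsHet(6.0, 0.5), default_grid)
    assert locus.points == []


def test_roots_match_asymptotic_closed_form(tall_grid):
    p = LagrangeParamsHet(alpha=-6.0, beta=1.0)
    locus = solve_locus(p, tall_grid, a_range=[1, 2, 3])
    assert locus.t_for_a(1.0) == pytest.approx(math.exp(6), rel=1e-6)
    assert locus.t_for_a(2.0) == pytest.approx(math.exp(6) / 2, rel=0.01)
    assert locus.t_for_a(3.0) == pytest.approx(math.exp(6) / 3, rel=0.01)


def test_every_root_satisfies_residual_tolerance_and_boundary(default_grid):
    p = LagrangeParamsHet(alpha=-5.0, beta=1.0)
    locus = solve_locus(p, default_grid)
    assert locus.points
    for (t, a), r in zip(locus.points, locus.residuals):
        assert t >= a >= 1
        assert abs(r) < 1e-6
        assert abs(residual(t, a, p, default_grid)) < 1e-6


def test_all_roots_reported_with_smallest_as_primary(default_grid):
    """Near the boundary a line can host a second root (the residual dips
    and recrosses); every root is reported and the primary is the smallest."""
    p = LagrangeParamsHet(alpha=-5.0, beta=1.0)
    locus = solve_locus(p, default_grid)
    by_line: dict[float, list[float]] = {}
    for t, a in locus.points:
        by_line.setdefault(a, []).append(t)
    assert by_line
    for a, ts in by_line.items():
        assert locus.t_for_a(a) == min(ts)
        assert len(set(ts)) == len(ts)


def test_pure_power_locus_slope_is_minus_beta():
    p = LagrangeParamsHet(alpha=-6.0, beta=1.3)
    pure = pure_power_locus(p, range(1, 20))
    ts = np.array([t for t, _ in pure.points])
    aa = np.array([a for _, a in pure.points])
    slope = np.polyfit(np.log(aa), np.log(ts), 1)[0]
    assert slope == pytest.approx(-1.3, abs=1e-12)
    assert pure.t_for_a(2.0) == pytest.approx(math.exp(6) / 2**1.3)


def test_departure_one_signed_and_vanishing(default_grid):
    """The full locus sits below the power law and converges onto it."""
    p = LagrangeParamsHet(alpha=-5.9, beta=1.0)
    full = solve_locus(p, default_grid)
    pure = pure_power_locus(p, range(1, default_grid.a_max + 1))
    prof = departure_profile(full, pure)
    assert prof
    gaps = {a: gap for a, _, gap in prof}
    assert all(g <= 1e-9 for g in gaps.values())  # one-signed: full below pure
    for a, t_full, gap in prof:
        if t_full / a >= 40:
            assert abs(gap) / t_full < 0.01


def test_departure_zero_on_single_letter_line(tall_grid):
    """For a = 1 both formulations are degenerate (dI/dt = 0): gap exactly 0."""
    p = LagrangeParamsHet(alpha=-6.0, beta=1.0)
    full = solve_locus(p, tall_grid, a_range=[1, 2])
    pure = pure_power_locus(p, [1, 2])
    gaps = {a: gap for a, _, gap in departure_profile(full, pure)}
    assert gaps[1.0] == pytest.approx(0.0, abs=1e-6)


def test_departure_requires_shared_range(default_grid):
    p = LagrangeParamsHet(alpha=-5.0, beta=1.0)
    full = solve_locus(p, default_grid, a_range=[2, 3])
    pure = pure_power_locus(p, [10, 11])
    with pytest.raises(ValueError):
        departure_profile(full, pure)


def test_scale_translation_invariance(tall_grid):
    """alpha -> alpha + c translates log t by -c in the asymptotic regime."""
    c = 0.3
    p0 = LagrangeParamsHet(alpha=-6.0, beta=1.0)
    p1 = LagrangeParamsHet(alpha=-6.0 + c, beta=1.0)
    l0 = solve_locus(p0, tall_grid, a_range=[2])
    l1 = solve_locus(p1, tall_grid, a_range=[2])
    assert math.log(l0.t_for_a(2.0)) - math.log(l1.t_for_a(2.0)) == pytest.approx(
        c, abs=1e-3
    )
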