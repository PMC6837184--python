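# cohsi

Tools for studying discrete systems — proteomes, software, digital music —
through the conservation of Hartley–Shannon information (CoHSI): the
observation that fixing a system's total token count `T` and total
information `I = Σ log N(tᵢ, aᵢ)` in a statistical-mechanics framework
predicts its component-length distribution, with no reference to what the
tokens mean.

The package is aimed at anyone who wants to reproduce or probe this class
of analysis at desk scale: exact counting of token arrangements, numerical
solution of the predicted distributions, and the statistical battery used
to test power-law tails in real data.

## What it computes

**Exact combinatorics.**  `N(t, a)` — the number of length-`t` strings over
an `a`-letter alphabet using every letter at least once — via both the
counting recursion and the inclusion–exclusion closed form, in
arbitrary-precision integers.  The component information is `log N(t, a)`
(nats), taken on the big integer so `N(300, 22)` and beyond are no problem.

**Heterogeneous solver.**  Root locus of the implicit length equation

    log t + α + β·dI/dt = 0

on a grid of exact node values with monotone interpolation.  For `t ≫ a`
this collapses to the pure power law `t = exp(−α − β log a)`; the full
locus departs below it near the origin, which is where the characteristic
sharp unimodal peak of component-length histograms comes from.

**Homogeneous solver.**  Rank/frequency solution `tᵢ = exp(−κ − η log i)`
— Zipf's law — under three log-factorial treatments (Stirling, Ramanujan,
exact digamma inversion).  The better treatments make sparsely populated
high ranks droop below the Zipf line, reproducing the drooping tail often
seen in rank data.

**Measurement and testing.**  Readers for FASTA proteomes, token streams
and note-event tables reduce every component to `(length, alphabet)`;
ccdfs, geometric binning, rank recategorisation and dual-alphabet pairing
describe the data; a discrete power-law MLE with KS-based cutoff selection
and semi-parametric bootstrap decides whether a power-law tail is plausible
(`p ≥ 0.1`).

**Synthetic generators.**  Seeded generators with known ground truth for
every pipeline stage, including uniform sampling over the exactly counted
admissible strings and exact discrete power-law samplers.

## Worked example

```python
import math
from cohsi import (count_exact, het_information, het_information_asymptotic,
                   build_grid, solve_locus, LagrangeParamsHet)
from cohsi.hom_solver import LagrangeParamsHom, solve_hom, droop_profile

print("N(5,2) =", count_exact(5, 2))
print("I(5,2) = %.4f nats" % het_information(5, 2))
print("t*log(a) = %.4f nats" % het_information_asymptotic(5, 2))

grid = build_grid()                       # exact nodes up to t=200, a=30
locus = solve_locus(LagrangeParamsHet(alpha=-5.9, beta=1.0), grid)
for a in (2.0, 3.0):
    print("a=%d: t=%.1f (pure power law %.1f)"
          % (a, locus.t_for_a(a), math.exp(5.9) / a))

stir = solve_hom(LagrangeParamsHom(-math.log(1000), 1.0, "stirling"), 40)
exact = solve_hom(LagrangeParamsHom(-math.log(1000), 1.0, "exact"), 40)
prof = droop_profile(exact, stir)
print("droop ratio at rank 1: %.6f, rank 40: %.6f"
      % (prof[0][1], prof[-1][1]))
```

prints

```
N(5,2) = 30
I(5,2) = 3.4012 nats
t*log(a) = 3.4657 nats
a=2: t=182.5 (pure power law 182.5)
a=3: t=121.7 (pure power law 121.7)
droop ratio at rank 1: 0.999500, rank 40: 0.979933
```

Reading the output: there are exactly 30 five-token strings that use both
letters of a two-letter alphabet, so the component's information is
log 30 ≈ 3.40 nats — strictly less than the unconstrained 5·log 2 ≈ 3.47,
and that deficit is the whole story of the unimodal peak.  With
`α = −5.9, β = 1` the solved locus already coincides with its power-law
asymptote at these `t/a` ratios.  In the homogeneous solution the exact
log-factorial treatment sits 0.05% below Zipf at the heavily populated
rank 1 but 2% below by rank 40: the droop grows as bins empty.

The same functionality is scriptable via the `cohsi` CLI
(`count`, `solve-het`, `solve-hom`, `measure`, `ccdf`, `rank`, `alphabets`,
`fit-tail`, `simulate`), e.g. `cohsi count --t 5 --a 2` → `30`.

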