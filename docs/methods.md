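# Methods

## The model

A discrete system is a set of *components*, each an ordered string of
*tokens* (a protein of amino-acid residues, a software function of language
tokens, a musical composition of notes).  Two numbers summarise a component:
its length `t` in tokens and its *unique alphabet* `a`, the number of
distinct tokens it actually uses.  The Hartley–Shannon information content of
a component is the natural log of the number of distinct admissible
arrangements of its tokens — token meaning plays no role.

### Heterogeneous systems

For a component required to use every one of its `a` letters at least once,
the number of admissible strings is the surjection-type count `N(t, a)`,
computed exactly here by two independent routes:

* the recursion `N(t, a; a) = a^t − Σ_{k<a} C(a, k) N(t, k; k)`, where
  `N(t, a; a′)` counts strings using exactly `a′` distinct letters of an
  `a`-letter alphabet;
* the inclusion–exclusion closed form `Σ_k (−1)^k C(a, k) (a − k)^t`.

Both run in arbitrary-precision integer arithmetic; floats appear only when
the final log is taken, and the log is taken on the big integer itself, so
values such as `N(300, 22)` (≈ 400 digits) are handled without overflow.
Conventional floating arithmetic fails well before that scale, which is why
exactness is non-negotiable here.

Treating the system in a statistical-mechanics frame — total tokens `T` and
total information `I` fixed by Lagrange multipliers `α` and `β`, component
contents varied at fixed per-component alphabets — the most likely length
distribution is the root locus of the implicit condition

```
log t + α + β · dI/dt = 0,     I(t, a) = log N(t, a).
```

For `t ≫ a`, `dI/dt → log a` and the condition collapses to the explicit
power law `t = exp(−α − β log a)`.  Because `dI/dt` approaches `log a`
strictly from above (for `a ≥ 2`), the full locus lies on one side of that
power law — at or below it — and converges onto it as `t/a` grows.  The
region between the two is the origin of the sharp unimodal peak observed in
component-length histograms: shorter components carry measurably less
information than `t log a` because keeping all `a` letters present removes
arrangements.

**Sign convention.**  Written literally, the condition with positive
multipliers of the magnitudes usually quoted for illustration (e.g.
`α = 6, β = 0.5`) places every asymptotic root at `t < 1`, outside the
physical domain `t ≥ a ≥ 1`.  `LagrangeParamsHet` therefore carries a
`sign_convention`: `as_printed` evaluates the condition literally (negative
`α` gives admissible loci for `β > 0`), `reflected` negates both
multipliers.  The discrepancy is surfaced rather than silently patched.

### Continuation and differentiation

The implicit equation needs `log N` and `dI/dt` at real `t`.  The package
evaluates `log N` exactly at every integer node `a ≤ t ≤ t_max`, applies
second-order central differences on the unit spacing (one-sided second-order
stencils at `t = a` and `t = t_max`), and interpolates both arrays per
alphabet line with a monotone-preserving piecewise cubic (PCHIP).  The
interpolant coincides with the exact values at the nodes, which is all the
root finder ultimately samples; monotone interpolation avoids spurious
oscillation between nodes.  An alternative would be symbolic continuation of
the unwound recursion via `Γ(n + 1)`; it agrees at integer nodes but the
alternating closed form evaluated in floats cancels catastrophically near
`t ≈ a`, so the exact-integer-plus-interpolation route is used instead.

Finite-difference truncation: on the `a = 2` line the exact derivative of
`log(2^t − 2)` is available analytically; the grid derivative agrees within
`2 × 10⁻²` for `t ≥ 5` and within `10⁻³` by `t = 40`.

Defaults: `t_max = 200`, `a_max = 30` — enough to enclose the unimodal
departure region before the asymptote takes over, while keeping the grid
build near-instant.  The guard ceiling is `t_max = 500`.

Root finding: the residual is scanned on integer nodes per alphabet line;
every sign change is bracketed and refined by Brent's method to
`|residual| < 10⁻⁶`.  Lines can genuinely lack roots (the smallest lengths
may admit no solution for a given `(α, β)`) — an empty line is simply
absent, and an entirely empty locus warns rather than raises.  Near the
boundary a line may host two roots (the residual dips and recrosses); all
are reported and the smallest is the primary, a deterministic tie-break.

### Homogeneous systems

When tokens are merely binned by kind — bin `i` holding `t_i`
indistinguishable tokens unique to that bin — the arrangement count is
`N_h = T! Π_i (1/i)^{t_i}`, so the information is
`log T! − Σ t_i log i`.  Bins are ranked descending (rank 1 = most
populated, the standard Zipf convention; the exponent `η` is then positive
for decaying laws), which also makes the information maximal-by-convention
since the largest bin multiplies `log 1 = 0`.  The stationarity condition
per rank is

```
d/dt [log t!] = −κ − η log i.
```

Three treatments of the left side are implemented:

* **stirling** — `d/dt[log t!] ≈ log t`, giving the closed form
  `t_i = exp(−κ − η log i)`: exact Zipf, log-log slope `−η`, `R² = 1` to
  machine precision;
* **ramanujan** — term-wise derivative of Ramanujan's approximation
  `log t! ≈ t log t − t + (1/6) log(8t³ + 4t² + t + 1/30) + (1/2) log π`,
  i.e. `log t + (24t² + 8t + 1) / (6(8t³ + 4t² + t + 1/30))`, solved by
  bracketing and Brent iteration;
* **exact** — the derivative of the exact log-gamma, `ψ(t + 1)` (digamma),
  inverted by guarded Newton iteration (trigamma slope, step-halving into
  the domain) to `|ψ(t + 1) − target| < 10⁻¹⁰`.

Because the correction terms satisfy `ψ(t+1) − log t ≥ ramanujan-correction
≥ 0` for all `t > 0`, the populations order as
`exact ≤ ramanujan ≤ stirling` at every rank, and the ratio
`t_exact / t_stirling` decreases monotonically with rank: the droop in the
tail emerges from the arithmetic of the log factorial alone.  At
`t ≈ 1000` the correction is of order `1/(2t)`, so the ratio is within
`10⁻³` of 1; sparsely populated bins droop visibly.  Ranks whose target
falls below `ψ(1)` admit no nonnegative population and are reported as
unpopulated (NaN), not as errors.

## Tail diagnostics

`loglog_ols` (via statsmodels) reports slope, standard error and adjusted
`R²` of `log₁₀ ccdf` on `log₁₀ x` over a stated range.  This is descriptive
only: ccdf points are strongly autocorrelated, so the nominal OLS standard
error understates the true slope scatter several-fold, and the discrete
ccdf has curvature near the origin even under an exact power law.  A slope
and `R² > 0.99` are necessary, never sufficient, evidence.

The inferential route is the standard Monte Carlo procedure for discrete
power laws:

* **MLE** — `p(x) = x^{−α} / ζ(α, xmin)` for integer `x ≥ xmin`; `α` by
  bounded scalar minimisation of the negative log-likelihood (tolerance
  `10⁻⁶`).  A continuous-approximation estimator
  `1 + n / Σ log(x / (xmin − ½))` is provided as a labelled fallback.
* **xmin** — scanned over distinct observed values (≥ 50 tail points per
  candidate), choosing the candidate minimising the Kolmogorov–Smirnov
  sup-distance between empirical and fitted tail ccdfs (both in the
  `P(X ≥ x)` convention, evaluated on either side of each step).
* **bootstrap** — semi-parametric: per replicate, below-`xmin` values are
  resampled empirically and the tail is drawn from the fitted law by exact
  inverse transform on the zeta ccdf; the exponent is refitted (xmin held
  fixed by default; full re-selection behind `refit_xmin=True`) and the
  replicate KS recorded.  `p` is the fraction of replicate KS values at
  least the observed one; the tail is *plausible* iff `p ≥ 0.1`.  A
  `binned=True` mode first collapses samples onto geometric-bin midpoints,
  mirroring pipelines that must bin very large datasets before
  bootstrapping; it is approximate and labelled as such.

Known limitation: the zeta-normalised discrete fit is not scale-equivariant.
A sample multiplied by 2 occupies only even integers, which no discrete
power law on all integers matches point-by-point, so the KS scan selects a
cutoff higher than twice the original rather than exactly twice.

## Synthetic data

The generators define the study conditions for every test:

* `sample_exact_alphabet_string(t, a)` — uniform over the `N(t, a)`
  admissible strings by rejection from the `a^t` unconstrained ones
  (acceptance probability `N/a^t`, bounded away from 0 for `t ≥ a`);
  uniformity is verified by chi-square against the exhaustive enumeration.
* `generate_powerlaw_lengths` — exact inverse transform on the zeta ccdf
  (grid to `10⁶`, bisection fallback above), used for tail-fitter
  calibration at exponent 2.5, `xmin = 5`, `n = 5 × 10⁴` — tail sizes at
  which the MLE's sampling error (≈ 0.007) sits comfortably inside the
  ±0.05 recovery band.
* `generate_dual_alphabet_corpus` — compositions over the 88-pitch,
  7-duration note vocabulary whose two alphabets `a′` (pitch only) and
  `a″` (pitch × duration) realise `a″ = round(c · a′^γ)` exactly, clipped
  to the feasible band `[a′, 7a′]`; the default pitch-alphabet range (5–45)
  keeps `γ = 1.5, c = 1` clip-free.  Multiplicative log-normal noise is
  optional.
* `enumerate_microstates` — exhaustive composition enumeration for tiny
  systems (`T ≤ 12, M ≤ 3`) with exact multinomial multiplicities,
  verifying by brute force that the modal macrostate is the
  maximum-multiplicity one the variational argument singles out.

All randomness flows through one named numpy `Generator`; fixed seeds give
byte-identical output.

What synthetic inputs do *not* emulate: real proteome or software corpora
mix the heterogeneous peak and tail with database-curation artefacts,
finite-alphabet saturation and non-equilibrium history.  Passing tests show
the machinery is correct and calibrated under its own stated conditions;
they do not certify any particular empirical dataset as power-law tailed.
Reproducing published corpus-scale slopes and bootstrap p-values requires
the multi-gigabyte external datasets themselves, for which the readers and
CLI provide the pipeline but not the data.

## Numerical and design choices

* Natural logs (nats) everywhere.
* Equality ties in rank recategorisation break by ascending length —
  deterministic and documented.
* ccdf convention is `P(X ≥ x)`, matching the discrete KS machinery.
* Geometric bin edges are `x_low · ratio^k`, half-open except the last
  (closed) bin; density is count/width.
* `hom_information` sorts internally, so it is order-invariant by
  construction.
* The bootstrap keeps each replicate's tail fittable by flooring the
  binomial tail draw at the 50-observation minimum; at calibration sizes
  the floor never binds.
* Problem sizes in the test suite (grids to `t_max = 450`, samples to
  `10⁵`, 50 bootstrap meta-replicates at `n_boot = 100`) were chosen as the
  smallest at which each property is comfortably resolved.
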