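# Methods

This note records the model assumptions, the parameter choices with their
rationale, the numerical schemes, and the known limitations of the
package.  It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Demographic model

Populations evolve in discrete unit time steps.  City `i` changes through
the balance

    N_i(t+1) = N_i(t) + v_i N_i(t) + Σ_j (J_ji − J_ij),

with per-capita vital rate `v_i = b_i − d_i` (migration from outside the
system may be absorbed into it) and person flows `J_ij = m_ij N_i`.  In
matrix form `N(t+1) = A N(t)` where the environment `A` carries
`1 + v_i − m_i_out` on the diagonal and the *transposed* migration
probabilities off it: **rows index destination, columns origin**.  Most
published origin/destination tables are origin-major; `build_environment`
transposes internally, and `validate_system` checks the assumptions
(non-negativity, strong connectivity, aperiodicity) under which a unique
positive leading eigenvector exists.

Long deterministic runs are integrated in `(x, log N_T)` coordinates
(share vector plus log total).  This is algebraically identical to
iterating raw sizes — the per-step total growth factor is accumulated in
log space — and avoids floating-point overflow for `t ≫ t*` when the
system grows exponentially.

### Flow decomposition and the self-consistent regime

Writing `J_ij = ((s_ij + δ_ij)/2)(N_j/N_T) N_i` makes flows bilinear in
origin and destination size.  The two parts are pinned by
`s_ij = m_ij/x_j + m_ji/x_i` and `δ_ij = m_ij/x_j − m_ji/x_i`; any global
rescaling with compensating share dependence is unidentifiable, so the
package fixes the scale by exactly these relations.  The symmetric part
cancels from the size dynamics (gravity flows, `δ = 0`, leave every city
unchanged); the antisymmetric drift gives the self-consistent share
dynamics `x_i ← [1 + v_i − v̄ − (δx)_i] x_i`.  Its fixed-point condition
is linear in `x`, so `solve_self_consistent` solves it by least squares
with the simplex constraint, falling back to a damped iteration of the
physical map (damping 0.5) when no interior solution exists and the
attractor is a boundary face.  Purely rotational drift fields cycle
rather than converge; the solver then warns and reports the residual —
this is the known failure mode, and Newton polishing was judged not worth
the complexity since the least-squares path already handles every case
with a solution.

## Symmetry-restored stochastic dynamics

`simulate_structure` draws, each step, i.i.d. zero-mean Gaussian vital
noise of scale `sigma` and an i.i.d. antisymmetric migration-drift matrix
with lognormal magnitudes and random signs (antisymmetry enforced exactly
by mirroring the upper triangle).  The relative growth rate
`ε_i = v_i − v̄ − (δx)_i` then has share-weighted mean exactly zero every
step, so the mean fitness is identically one (neutrality) and temporal
means vanish without tuning.  An AR(1) option for the vital noise exists
(`vital_autocorrelation`), defaulting to zero: the temporal correlation of
the rates is not constrained by the theory, and i.i.d. is the minimal
assumption.

Default noise scales: `sigma = 0.05` per √step; lognormal magnitudes with
log-sd 1.0 and log-mean `ln(0.036) − 0.5`, i.e. mean magnitude 0.036, so
that typical out-migration is about 1.8% per step — the observed annual
inter-metropolitan migration fraction in the US.  Growth factors that a
rare noise draw would push non-positive are clipped to 1e-3 and counted in
the run report (a handful per 10⁵ steps at default parameters).

### Per-city volatility normalization

On a closed simplex the subtraction of the share-weighted mean growth
correlates every city with the aggregate: the raw construction gives city
`i` the variance `σ_i²(1−x_i)² + Σ_{j≠i} σ_j² x_j² (+ migration term)`,
which suppresses the volatility of the largest city by `(1−x_1)²` — about
35% when the top share is 0.2.  That violates the premise of the
stationary theory (size-independent growth volatility) and visibly
condenses mass into the top city at `n = 100`.  By default the package
therefore rescales `ε_i` per city so its standard deviation equals the
prescribed `σ_i(x)` exactly (`normalize_volatility=False` restores the raw
construction).  The renormalization of the simplex after the update keeps
the mean-fitness identity exact either way.

### Lower boundary: the ghost-city rule

Driftless multiplicative noise has no stationary density on `(0, ∞)`: the
log-normal transient drifts to ever smaller shares.  A lower boundary
`x_m` mimics the compensating probability current from the unresolved
Zipfian hierarchy of smaller towns.  When a city falls below `x_m` it is
reset to its previous share and the excess is removed from the other
cities, iterating so nobody is pushed below the floor.  Two redistribution
modes exist:

* `proportional` (default): the others shrink by a common factor — the
  share-space image of resetting the city's absolute *size* while the
  total absorbs the difference.  This correction is growth-neutral.
* `uniform`: equal absolute amounts are removed.  In share space this is
  an absolute loss independent of size, i.e. a strong relative drag on
  small cities; it is kept for comparison and measurably flattens the
  emergent rank-size profile (fitted exponent ≈ 0.8 instead of ≈ 1).

The floor's default *value* is the mass-consistency point computed by
`zipf_consistent_floor`: on a closed simplex the realized stationary
density exponent is, to good accuracy, the `β` whose truncated power law
`c/x^β` on `[x_m, x_M]` carries total mean mass `n·E[x] = 1`.  Solving
that balance for `x_m` at the target exponent (`β = 2 − alpha`) makes the
target law self-consistent; at `n = 100` the Zipf floor is `x_m ≈ 0.00154`,
about 25% below the smallest city of a discrete 100-city Zipf hierarchy
(`≈ 0.00193`, also available by setting `x_min` explicitly — with that
choice the balance point moves to `β ≈ 2.10` and the fitted rank exponent
to `z ≈ 0.90`).  The upper boundary defaults to `x_M = 1` (total
concentration), is never enforced, and is only monitored; it is not
reached at default parameters.

### What the runs show — and the known finite-size bias

With these defaults a 100-city run at `sigma = 0.05` over 10⁵ steps yields
a rank-aligned time-averaged rank-size exponent `z ≈ 0.94–1.00` over ranks
5–50 (seed-dependent), with individual snapshots fluctuating much further
from Zipf than their cumulative average — the signature property of the
neutral regime.

One systematic remains and is documented rather than hidden: refilling
floor-violating cities necessarily skims mass from the bulk, a small
common downward drift relative to the fixed floor that steepens the
realized density exponent in proportion to the mass hovering near the
floor.  For the Zipf target the effect is ~+0.02 on the density exponent;
for steep targets (`2 − alpha = 2.5`, where most cities live near the
floor) it reaches ~+0.11.  The bias is unchanged between `sigma = 0.08`
and `0.04`, i.e. it is a continuum property of the closed `n`-city system,
not a time-step artifact, and it sets the accuracy limit of the
Gibrat-violation exponent recovery (`2 − alpha` recovered to ≈1% for
`alpha ≥ 0`, ≈4% at `alpha = −0.5`).  Uncertainty for these exponent fits
is quoted from replicate seeds × fit windows combined with the regression
SE, because pooled snapshots are autocorrelated and the regression SE
alone is an underestimate.

### Extinction times

`extinction_times` measures mean first passage to the floor with the
boundary disabled (absorbing).  The log share of a rank-`r` city starts
`ln(r_max/r)` above the floor and performs a random walk with drift
`−σ²/2` per step, so the exact Monte-Carlo mean is
`2 ln(r_max/r)/σ²` (Wald identity).  The companion closed-form predictor
returned alongside is the growth-reversal scale `t_r·ln(r_max/r)` with
`t_r = 1/(2σ²)` — a characteristic time, a factor 4 below the mean
first-passage time; both numbers are reported so the distinction is
explicit.

## Fokker–Planck solutions

Share densities obey `dP/dt = d²/dx²[(σ²/2)x²P]` (this convention, with
the 1/2, is used throughout; results quoted without it correspond to the
relabeling `σ² → σ²/2`).  Closed forms: the zero-current stationary law
`α₁/x²` with `α₁ = x_M x_m/(x_M − x_m)`; the constant-current law
`1/(x ln(x_M/x_m))`; and the boundary-free lognormal transient with
log-mean `ln x₀ − (σ²/2)Δt` and log-variance `σ²Δt` (implemented through
`scipy.stats.lognorm`; only these two moments are treated as
authoritative for the transient's normalization).

The numerical solver is a conservative finite volume on a grid uniform in
`log x` with geometric-mean cell centres.  Face fluxes are difference
quotients of `q = (σ²/2)x²P` between neighbouring centres, so zero-current
boundaries conserve mass to rounding and the *discrete* stationary state
telescopes to exactly `α₁/x²` at the cell centres with the continuum
normalization constant — the measured log-log slope is −2 to rounding.
Time stepping is the theta scheme: implicit Euler (`theta = 1`, L-stable)
for marching to stationarity, Crank–Nicolson (`theta = 0.5`) with small
steps for transient accuracy; both are unconditionally stable, so the step
size is purely an accuracy knob.  For the constant-current boundary the
flux value returned by `matched_current` makes the discrete 1/x law carry
unit mass, so evolution from any unit-mass start converges to it exactly.
Absorbing-floor mode uses a zero ghost density below the lower face.

In log coordinates `y = ln(x/x₀)`, `τ = (σ²/2)(t−t₀)` the generator is
`P'' + 3P' + 2P`; its null modes `e^{−2y}` and `e^{−y}` are the two
stationary laws (the constant term must be `+2P` for this to hold, and the
factorization `P = e^{−3y/2 − τ/4} g` with `dg/dτ = g''` checks only under
that form; `log_space_operator` exposes the discretized generator with
fourth-order stencils so both modes are annihilated below 1e-8 at moderate
grid spacing, where float64 cancellation is still negligible).  The sine
eigenexpansion of `g` uses the standard Dirichlet basis `k_n = πn/L` with
decay `e^{−k_n²τ}`, which satisfies the factorized equation and the
boundary conditions exactly and reconstructs smooth initial profiles to
<1% with 64 modes.  A `basis="printed"` variant with `k_n = 2πn/L`, a
`−3τ` argument shift and `e^{−(k_n²−2)τ}` decay is retained for
comparison; it spans only the odd-about-midpoint part of a profile and
breaks the boundary conditions for `τ > 0`, so the Dirichlet basis (or the
finite-volume solver as ground truth) should be used for quantitative
work.

## Diagnostics

Information measures use base-2 logarithms (bits).  KL terms with
`P_i = 0` contribute zero; reference entries are floored at 1e-15 with a
warning, since boundary-hugging structures can reach machine-small
shares.  Rank-size fits regress `log N` on `log r` over a window
defaulting to ranks `[5, n/2]`, avoiding the systematic deviations at both
extremes; cross-snapshot statistics are rank-aligned by default (each
snapshot sorted before averaging), with identity alignment available.
The binned mutual-information estimator is a plug-in with the usual upward
bias of order `(rows−1)(cols−1)/(2N ln 2)`; it is a convenience, not a
headline feature.

## Synthetic data

The generators emulate the structure of the study system, not any
particular data set: near-equal or Zipfian initial populations;
exchangeable environments with small relative noise (whose stationary
structure is uniform by symmetry); gravity environments from coordinates
sampled in the unit square with out-migration rescaled to a target (0.2
per step by default); sparse random migration graphs regenerated until
strongly connected.  Flow tables are header-bearing CSV
(`origin_id, destination_id, count`) with a unit-to-aggregate crosswalk;
intra-aggregate moves are dropped from migration (an integrated labor
market is one city), cross-aggregate counts are conserved exactly, and
per-capita rates are flows over origin population — a 1000-person unit
sending 18 movers has rate 0.018.  What passing tests on these fixtures do
*not* show: real migration tables have reporting gaps (tax-filer coverage
~85%), temporally correlated rates, and entry/exit of units — none of
which the generators emulate; conclusions about real systems require the
optional empirical path with real tables.

## Problem sizes

Defaults were chosen as the smallest sizes at which the asymptotic
behavior is cleanly visible: 100 cities (the scale of a national
metropolitan system), 10⁵ steps with 2×10⁴ burn-in for the
symmetry-restored runs (several hundred growth-reversal times
`t_r = 1/(2σ²) = 200` at `sigma = 0.05`), 512 finite-volume cells over
four decades of share, 10⁴ Monte-Carlo paths for the transient moments,
and 400 paths per rank for extinction times.
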