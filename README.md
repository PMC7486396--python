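# citydemog

Demographic dynamics of city-size distributions: a simulator and analytics
library for deriving urban rank-size laws — Zipf's law in particular — from
the fundamental balance of births, deaths and inter-city migration.

## The science

City sizes across many urban systems follow, roughly, the rank-size rule

    N(r) = N0 / r**z,      z ≈ 1          (Zipf's law)

equivalently a Pareto density P(N) ∝ 1/N². Rather than postulating
proportional growth at some mesoscopic scale, this package starts from the
demographic bookkeeping of a system of `n` cities.  The population vector
projects forward through the *environment* matrix

    A[i][i] = 1 + v_i − m_i_out        A[i][j] = m[j→i]   (i ≠ j)

(`v_i` per-capita vital rate, `m[j→i]` migration probabilities; rows index
destination).  Three regimes follow:

* **Static environment.** `N(t) = A**t N(0)` converges to the leading
  eigenvector of `A` for any start (strong ergodicity), on a time scale
  `t* = 1/ln(λ0/|λ1|)` set by the spectral gap — a dimensional reduction to
  a single degree of freedom.  The result generically looks nothing like
  Zipf's law.
* **Self-consistent nonlinear environment.** Writing migration as
  `J_ij = ((s_ij + δ_ij)/2)(N_j/N_T)N_i` splits flows into a symmetric part
  `s` (which cancels from the dynamics, and reduces to the gravity law
  `J_ij = G N_i N_j / d_ij**γ` when `δ = 0`) and an antisymmetric drift
  `δ`, giving `x_i(t+1) = [1 + v_i − v̄ − (δx)_i] x_i(t)` for the share
  vector `x = N/N_T`.  Persistent `v` or `δ` select a particular hierarchy.
* **Symmetry-restored stochastic environment.** When the vital and
  migration rates fluctuate with vanishing temporal means, every city's
  relative growth rate `ε_i` is zero on average (fitness `w_i = 1 + ε_i`,
  share-weighted mean exactly one: neutrality).  The share density then
  obeys a Fokker–Planck equation `dP/dt = d²/dx²[(σ²/2)x²P]`; with zero
  probability current through the boundaries `[x_m, x_M]` the stationary
  law is `P = α₁/x²` with `α₁ = x_M·x_m/(x_M − x_m)` — Zipf — while a
  constant current gives `P ∝ 1/x`.  The lower boundary stands in for a
  Zipfian "ghost" hierarchy of unresolved small towns; departures from
  Zipf are selection and are measured in bits (KL divergence, surprise).

The package implements all three regimes, the exact and numerical
Fokker–Planck solutions, the information diagnostics, seeded scenario
generators, and readers for empirical-style origin/destination flow tables
with unit-to-aggregate (county-to-metro) crosswalks.

## Worked example

```python
import numpy as np
import citydemog as cd

# a 2-city environment: 10% move 1→2, 20% move 2→1, no vital surplus
env = cd.build_environment(cd.DemographicRates.from_vital([0.0, 0.0]),
                           cd.MigrationModel(np.array([[0.0, 0.1],
                                                       [0.2, 0.0]])))
ss = cd.spectral_summary(env)
print(ss.leading_vector, ss.t_star)

# symmetry-restored stochastic run, 100 cities
cfg = cd.StochasticConfig(n_cities=100, sigma=0.05,
                          n_steps=40_000, burn_in=10_000, seed=3)
run = cd.simulate_structure(cfg)
avg = cd.time_average_structure(run.structures,
                                burn_in=int(np.searchsorted(run.times,
                                                            cfg.burn_in)))
fit = cd.fit_ranksize(avg.mean_shares, window=(5, 50))
print(f"z = {fit.exponent:.3f} +/- {fit.stderr:.3f}; "
      f"KL(avg || Zipf) = {avg.final_kl:.4f} bits")
```

prints

```
[0.66666667 0.33333333] 2.8036732520571286
z = 1.010 +/- 0.001; KL(avg || Zipf) = 0.0245 bits
```

The two-city system settles into a 2:1 hierarchy (the leading eigenvector)
within a few units of `t* ≈ 2.8` steps.  The stochastic run's time-averaged
rank-size profile has exponent `z ≈ 1` over mid-ranks — Zipf's law emerging
from neutral demographic noise — and sits 0.02 bits from the exact Zipf
reference, even though individual snapshots fluctuate much further away.

A command-line interface wraps the main pipelines:

```
citydemog gen-scenario --name fig1b --seed 7 --out scen/
citydemog simulate-stochastic --config cfg.json --seed 1 --out run/
citydemog diagnose --trajectory run/trajectory.csv --out diag/
citydemog fp-stationary --x-min 1e-4 --kind zipf --out zipf.csv
citydemog fp-evolve --x-min 1e-4 --sigma 0.1 --t-final 40000 --out dens.csv
citydemog aggregate --flows county_flows.csv --crosswalk cw.csv --out msa.csv
```

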