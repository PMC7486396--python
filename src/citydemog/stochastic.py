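"""Stochastic share dynamics: symmetry restoration and emergent Zipf law.

Each step the share vector is multiplied city-wise by a fitness
``w_i = 1 + eps_i`` where the relative growth rate

    eps_i = vital_i - mean(vital) - (delta(t) @ x)_i

is built from fresh zero-mean Gaussian vital noise and a fresh antisymmetric
migration-drift matrix ``delta(t)`` with lognormal magnitudes and random
signs.  By construction the share-weighted mean of ``eps`` vanishes at every
step (the antisymmetric quadratic form is identically zero), so the mean
fitness is exactly one — the dynamics is neutral — and over long runs every
city's temporal mean growth rate also vanishes: no city is persistently
preferred.  Under these symmetry-restored conditions the time-averaged
rank-size distribution approaches Zipf's law.

Two finite-system corrections matter at ``n ~ 100`` cities and are applied
by default (both configurable off):

* **Volatility normalization.**  Subtracting the share-weighted mean growth
  suppresses the variance of the largest city by ``(1 - x_1)**2`` (about 35%
  when the top share is 0.2), breaking the premise that every city has the
  same growth volatility and biasing mass toward the top.  The relative
  growth rates are therefore rescaled per city to the prescribed volatility
  ``sigma_i(x)``.
* **Self-consistent floor.**  On a closed simplex the realized stationary
  density exponent is the one whose truncated power law carries total mass
  one; :func:`zipf_consistent_floor` solves that mass balance, placing the
  floor where the target law (Pareto exponent ``2 - alpha``) is
  self-consistent.  The discrete Zipf-minimum floor ``max(x0)/n`` lies about
  25% above it at ``n = 100`` and drives the balance point away from Zipf.

A lower boundary on shares is essential in any case: without it the
multiplicative noise drives the distribution towards ever smaller shares
(the lognormal spreading of driftless geometric growth).  The boundary rule
emulates the probability inflow from a Zipfian "ghost" population of cities
below the smallest resolved size: a city falling under the floor ``x_m`` is
reset to its previous share and the excess is removed from the cities above
the floor — proportionally by default (the growth-neutral reading of
resetting a city's *size* while the total absorbs the difference), or in
equal absolute amounts with ``redistribution='uniform'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .diagnostics import kl_divergence, zipf_reference
from .environments import DemographyError

__all__ = [
    "StochasticConfig",
    "StochasticRun",
    "zipf_consistent_floor",
    "simulate_structure",
    "enforce_lower_boundary",
    "simulate_gbm",
    "RankSizeAverage",
    "time_average_structure",
    "ExtinctionTimes",
    "extinction_times",
]

#: default lognormal log-mean for migration-drift magnitudes: mean magnitude
#: exp(mu + 1/2) = 0.036, putting typical out-migration near 1.8% per step
MIGRATION_LOG_MEAN = float(np.log(0.036) - 0.5)


def _truncated_pareto_mean(beta: float, x_m: float, x_M: float) -> float:
    """Mean of the normalized density ``c / x**beta`` on ``[x_m, x_M]``."""
    if abs(beta - 2.0) < 1e-12:
        c = x_m * x_M / (x_M - x_m)
        return c * np.log(x_M / x_m)
    if abs(beta - 1.0) < 1e-12:
        return (x_M - x_m) / np.log(x_M / x_m)
    c = (beta - 1.0) / (x_m ** (1.0 - beta) - x_M ** (1.0 - beta))
    return c * (x_M ** (2.0 - beta) - x_m ** (2.0 - beta)) / (2.0 - beta)


def zipf_consistent_floor(n_cities: int, exponent: float = 2.0,
                          x_max: float = 1.0) -> float:
    """Lower share boundary at which the target stationary law is mass-consistent.

    Solves ``n * E[x | density ~ x**(-exponent) on [x_m, x_max]] = 1`` for
    ``x_m``.  For the Zipf case (``exponent = 2``) the result is of the order
    of the smallest city of a Zipf hierarchy, ``~ x_top / n``; using the
    mass-balanced value rather than the discrete Zipf minimum makes the
    zero-current law the self-consistent stationary state of the closed
    simplex.
    """
    if n_cities < 2:
        raise DemographyError("need at least two cities")

    def imbalance(xm: float) -> float:
        return n_cities * _truncated_pareto_mean(exponent, xm, x_max) - 1.0

    hi = x_max / n_cities * (1.0 - 1e-9)
    return float(brentq(imbalance, 1e-12, hi))


@dataclass(frozen=True)
class StochasticConfig:
    """Parameters of a symmetry-restored stochastic run.

    ``sigma`` is the per-sqrt(step) volatility of the relative growth rate;
    ``size_exponent`` (alpha) makes it size-dependent,
    ``sigma_i**2 = sigma**2 (x_i / reference_share)**(-alpha)``, tilting the
    stationary density exponent from 2 to ``2 - alpha``.  ``x_min = None``
    selects the mass-balanced floor :func:`zipf_consistent_floor` at run
    time.
    """

    n_cities: int = 100
    n_steps: int = 100_000
    burn_in: int = 20_000
    sigma: float = 0.05
    size_exponent: float = 0.0
    reference_share: float | None = None
    migration_noise: bool = True
    migration_log_mean: float = MIGRATION_LOG_MEAN
    migration_log_sd: float = 1.0
    vital_autocorrelation: float = 0.0
    normalize_volatility: bool = True
    redistribution: str = "proportional"
    x_min: float | None = None
    x_max: float = 1.0
    enforce_boundary: bool = True
    seed: int = 0
    record_every: int = 1

    def __post_init__(self):
        if self.n_cities < 2:
            raise DemographyError("need at least two cities")
        if not 0 < self.n_steps:
            raise DemographyError("n_steps must be positive")
        if not 0 <= self.burn_in < self.n_steps:
            raise DemographyError("burn_in must lie in [0, n_steps)")
        if self.sigma < 0:
            raise DemographyError("sigma must be non-negative")
        if self.x_min is not None and not 0 < self.x_min < 1.0 / self.n_cities:
            raise DemographyError("x_min must lie in (0, 1/n_cities)")
        if not 1.0 / self.n_cities <= self.x_max <= 1.0:
            raise DemographyError("x_max must lie in [1/n_cities, 1]")
        if not -1.0 < self.vital_autocorrelation < 1.0:
            raise DemographyError("vital autocorrelation must lie in (-1, 1)")
        if self.redistribution not in ("proportional", "uniform"):
            raise DemographyError("redistribution must be 'proportional' or 'uniform'")


@dataclass
class StochasticRun:
    """Recorded output of :func:`simulate_structure`."""

    config: StochasticConfig
    times: np.ndarray
    structures: np.ndarray
    x_min: float
    clip_count: int = 0
    boundary_events: int = 0
    x_max_hits: int = 0

    @property
    def n_cities(self) -> int:
        return self.structures.shape[1]

    def recorded_after_burn_in(self) -> np.ndarray:
        return self.structures[self.times >= self.config.burn_in]

    def report(self) -> dict:
        return {
            "n_cities": self.n_cities,
            "n_steps": int(self.config.n_steps),
            "sigma": self.config.sigma,
            "x_min": self.x_min,
            "clip_count": int(self.clip_count),
            "boundary_events": int(self.boundary_events),
            "x_max_hits": int(self.x_max_hits),
            "seed": int(self.config.seed),
        }


def _clipped_zipf_init(n: int, x_m: float) -> np.ndarray:
    """Zipf hierarchy with its tail clipped at the floor, renormalized.

    The largest ``k`` cities keep Zipf proportions scaled by a common
    factor; the rest sit exactly at the floor; ``k`` is the largest count
    for which the scaled rank-``k`` share still clears the floor.
    """
    z = zipf_reference(n)
    cum = np.cumsum(z)
    for k in range(n, 0, -1):
        c = (1.0 - (n - k) * x_m) / cum[k - 1]
        if c <= 0:
            continue
        if c * z[k - 1] >= x_m - 1e-15:
            out = np.full(n, x_m)
            out[:k] = c * z[:k]
            return out
    raise DemographyError("floor too high for any hierarchy on the simplex")


def simulate_structure(cfg: StochasticConfig, x0=None) -> StochasticRun:
    """Run the symmetry-restored stochastic share dynamics.

    Starts from a Zipf hierarchy unless ``x0`` is given.  Each step draws
    fresh vital noise and an antisymmetric migration drift, rescales the
    relative growth rates to the prescribed per-city volatility (see module
    notes), applies the multiplicative update, renormalizes the simplex and
    enforces the lower boundary.  Growth factors that would become
    non-positive are clipped (counted in the run report).  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cities
    if cfg.x_min is not None:
        x_m = cfg.x_min
    else:
        x_m = zipf_consistent_floor(n, 2.0 - cfg.size_exponent, cfg.x_max)
    if x0 is None:
        x = _clipped_zipf_init(n, x_m)
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.size != n:
            raise DemographyError("x0 has wrong length")
        x = x / x.sum()
        if np.any(x < x_m - 1e-12):
            raise DemographyError("initial structure violates the lower boundary")
        x = np.maximum(x, x_m)
        x /= x.sum()
    x_ref = cfg.reference_share if cfg.reference_share is not None else 1.0 / n
    alpha = cfg.size_exponent
    rho = cfg.vital_autocorrelation
    iu = np.triu_indices(n, 1)
    n_pairs = iu[0].size
    delta = np.zeros((n, n))
    # second moment of a signed lognormal magnitude
    v_mig = (np.exp(2.0 * cfg.migration_log_mean + 2.0 * cfg.migration_log_sd**2)
             if cfg.migration_noise else 0.0)

    n_rec = cfg.n_steps // cfg.record_every + 1
    times = np.empty(n_rec, dtype=int)
    structures = np.empty((n_rec, n))
    times[0], structures[0] = 0, x
    rec = 1

    clip_count = 0
    boundary_events = 0
    x_max_hits = 0
    z = np.zeros(n)  # standardized AR(1) innovation state
    for t in range(1, cfg.n_steps + 1):
        innov = rng.standard_normal(n)
        z = rho * z + np.sqrt(1.0 - rho * rho) * innov if rho else innov
        sigma_i = (np.full(n, cfg.sigma) if alpha == 0
                   else cfg.sigma * (x / x_ref) ** (-alpha / 2.0))
        vital = sigma_i * z
        eps = vital - float(vital @ x)
        if cfg.migration_noise:
            mags = rng.lognormal(cfg.migration_log_mean, cfg.migration_log_sd,
                                 n_pairs)
            vals = mags * np.where(rng.random(n_pairs) < 0.5, 1.0, -1.0)
            delta[iu] = vals
            delta[iu[1], iu[0]] = -vals
            eps = eps - delta @ x
        if cfg.normalize_volatility and cfg.sigma > 0:
            s2x2 = sigma_i**2 * x**2
            var_i = (sigma_i**2 * (1.0 - x) ** 2 + (s2x2.sum() - s2x2)
                     + v_mig * (float(x @ x) - x**2))
            target = sigma_i**2 + v_mig * float(x @ x)
            eps = eps * np.sqrt(target / var_i)
        w = 1.0 + eps
        bad = w <= 0
        if bad.any():
            clip_count += int(bad.sum())
            w = np.where(bad, 1e-3, w)
        y = w * x
        y /= y.sum()
        if cfg.enforce_boundary:
            viol = y < x_m
            if viol.any():
                boundary_events += int(viol.sum())
                y = enforce_lower_boundary(y, x, x_m,
                                           redistribution=cfg.redistribution)
        if y.max() > cfg.x_max + 1e-12:
            x_max_hits += 1  # monitored only; upper bound never enforced
        x = y
        if t % cfg.record_every == 0:
            times[rec], structures[rec] = t, x
            rec += 1
    if clip_count:
        warnings.warn(f"clipped {clip_count} non-positive growth factors", stacklevel=2)
    return StochasticRun(config=cfg, times=times[:rec], structures=structures[:rec],
                         x_min=x_m, clip_count=clip_count,
                         boundary_events=boundary_events, x_max_hits=x_max_hits)


def enforce_lower_boundary(x_new, x_prev, x_m: float, max_sweeps: int = 100,
                           redistribution: str = "proportional") -> np.ndarray:
    """Apply the ghost-city lower-boundary rule to a proposed share vector.

    Cities that fell below ``x_m`` are restored to their previous share; the
    excess is removed from the remaining cities — scaled down by a common
    factor (``redistribution='proportional'``, the default: equivalent to
    resetting the city's absolute size while the total absorbs the change)
    or in equal absolute amounts (``'uniform'``).  Either way the sweep
    repeats whenever the removal pushes another city under the floor.  The
    result sums to one to within rounding and every entry is at least
    ``x_m``.
    """
    x_new = np.asarray(x_new, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    if x_new.shape != x_prev.shape:
        raise DemographyError("share vectors differ in length")
    if np.any(x_prev < x_m - 1e-12):
        raise DemographyError("previous structure already violates the floor")
    if redistribution not in ("proportional", "uniform"):
        raise DemographyError("redistribution must be 'proportional' or 'uniform'")
    floored = x_new < x_m
    if not floored.any():
        return x_new.copy()
    out = x_new.copy()
    for _ in range(max_sweeps):
        free = ~floored
        if not free.any():
            raise DemographyError("infeasible boundary enforcement: all cities at the floor")
        out[floored] = x_prev[floored]
        out[free] = x_new[free]
        excess = out.sum() - 1.0
        if redistribution == "proportional":
            out[free] *= 1.0 - excess / out[free].sum()
        else:
            out[free] -= excess / free.sum()
        newly = free & (out < x_m)
        if not newly.any():
            return out
        floored |= newly
    raise DemographyError("boundary enforcement did not settle within the sweep limit")


def simulate_gbm(x0: float, sigma: float, n_steps: int, n_paths: int,
                 seed: int = 0, scheme: str = "exact") -> tuple[np.ndarray, np.ndarray]:
    """Driftless geometric Brownian motion paths (unit time step).

    ``scheme='exact'`` samples the exponential solution, whose log increments
    are Gaussian with mean ``-sigma**2/2`` and variance ``sigma**2`` per
    step; ``scheme='euler'`` applies the multiplicative Euler update
    ``x <- x (1 + sigma xi)``.  Returns ``(times, paths)`` with paths of
    shape ``(n_paths, n_steps + 1)``.
    """
    if x0 <= 0 or sigma < 0:
        raise DemographyError("x0 must be positive and sigma non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(n_steps + 1)
    if scheme == "exact":
        incr = rng.normal(-0.5 * sigma**2, sigma, size=(n_paths, n_steps))
        logx = np.concatenate([np.zeros((n_paths, 1)), np.cumsum(incr, axis=1)], axis=1)
        paths = x0 * np.exp(logx)
    elif scheme == "euler":
        factors = 1.0 + sigma * rng.standard_normal((n_paths, n_steps))
        paths = x0 * np.concatenate(
            [np.ones((n_paths, 1)), np.cumprod(factors, axis=1)], axis=1)
    else:
        raise ValueError("scheme must be 'exact' or 'euler'")
    return times, paths


@dataclass
class RankSizeAverage:
    """Rank-aligned time average of structure snapshots with KL diagnostics."""

    mean_shares: np.ndarray
    cumulative_kl: np.ndarray
    snapshot_kl: np.ndarray

    @property
    def final_kl(self) -> float:
        return float(self.cumulative_kl[-1])


def time_average_structure(snapshots, burn_in: int = 0,
                           align: str = "rank") -> RankSizeAverage:
    """Average structure snapshots over time (rank-aligned by default).

    ``snapshots`` is an array of share vectors (rows = times); the first
    ``burn_in`` rows are discarded.  Rank alignment sorts each snapshot
    descending before averaging, so the result is the mean rank-size
    profile.  Also returns the per-snapshot KL to Zipf and the KL of the
    cumulative running average — the trace that reveals how the time average
    approaches Zipf even while individual snapshots fluctuate away from it.
    """
    snaps = np.atleast_2d(np.asarray(snapshots, dtype=float))[burn_in:]
    if snaps.shape[0] < 1:
        raise DemographyError("no snapshots left after burn-in")
    if align == "rank":
        snaps = -np.sort(-snaps, axis=1)
    elif align != "identity":
        raise ValueError("align must be 'rank' or 'identity'")
    counts = np.arange(1, snaps.shape[0] + 1, dtype=float)[:, np.newaxis]
    prefix = np.cumsum(snaps, axis=0) / counts
    ref = zipf_reference(snaps.shape[1])
    cum_kl = np.array([kl_divergence(row, ref) for row in prefix])
    snap_kl = np.array([kl_divergence(row, ref) for row in snaps])
    return RankSizeAverage(mean_shares=prefix[-1], cumulative_kl=cum_kl,
                           snapshot_kl=snap_kl)


@dataclass
class ExtinctionTimes:
    """Monte-Carlo first-passage times through the lower boundary."""

    ranks: np.ndarray
    log_ratio: np.ndarray          # ln(r_max / r)
    mc_mean: np.ndarray
    mc_stderr: np.ndarray
    predicted: np.ndarray          # closed-form t_r * ln(r_max/r)
    censored: np.ndarray
    horizon: int


def extinction_times(sigma: float, r_max: int, ranks, n_paths: int = 200,
                     horizon: int | None = None, seed: int = 0,
                     block: int = 4096) -> ExtinctionTimes:
    """Mean first-passage time of a rank-``r`` city to the share floor.

    With boundary enforcement disabled the floor is absorbing.  A city of
    initial rank ``r`` in a Zipf hierarchy sits ``ln(r_max/r)`` above the
    floor in log share, and its log share performs a random walk with drift
    ``-sigma**2/2`` per step, so passage times grow with the log of the
    initial rank advantage.  The companion closed-form predictor is the
    growth-reversal estimate ``t_r ln(r_max/r)`` with ``t_r = 1/(2 sigma**2)``;
    note it is a characteristic scale, not the Monte-Carlo mean (the exact
    mean of the drifted walk is ``2 ln(r_max/r)/sigma**2``).

    Paths not absorbed within ``horizon`` steps are censored (counted and
    excluded from the mean).
    """
    from .fokker_planck import characteristic_times

    if sigma <= 0:
        raise DemographyError("sigma must be positive")
    ranks = np.atleast_1d(np.asarray(ranks, dtype=int))
    if np.any((ranks < 1) | (ranks > r_max)):
        raise DemographyError("ranks must lie in [1, r_max]")
    log_ratio = np.log(r_max / ranks.astype(float))
    if horizon is None:
        horizon = int(20 * (log_ratio.max() + 1.0) / sigma**2) + 100
    rng = np.random.default_rng(seed)
    mc_mean = np.empty(ranks.size)
    mc_stderr = np.empty(ranks.size)
    censored = np.zeros(ranks.size, dtype=int)
    drift, step_sd = -0.5 * sigma**2, sigma
    for k, L in enumerate(log_ratio):
        if L <= 0:
            mc_mean[k], mc_stderr[k] = 0.0, 0.0
            continue
        hit = np.full(n_paths, -1, dtype=np.int64)
        y = np.zeros(n_paths)
        alive = np.arange(n_paths)
        t0 = 0
        while alive.size and t0 < horizon:
            nsteps = min(block, horizon - t0)
            incr = rng.normal(drift, step_sd, size=(alive.size, nsteps))
            walk = y[alive, np.newaxis] + np.cumsum(incr, axis=1)
            crossed = walk <= -L
            any_cross = crossed.any(axis=1)
            first = np.argmax(crossed, axis=1)
            hit[alive[any_cross]] = t0 + first[any_cross] + 1
            y[alive] = walk[:, -1]
            alive = alive[~any_cross]
            t0 += nsteps
        done = hit >= 0
        censored[k] = int(np.count_nonzero(~done))
        if done.any():
            mc_mean[k] = float(hit[done].mean())
            mc_stderr[k] = float(hit[done].std(ddof=1) / np.sqrt(done.sum())) \
                if done.sum() > 1 else np.inf
        else:
            mc_mean[k], mc_stderr[k] = np.nan, np.nan
    predicted = np.array([characteristic_times(sigma, r_max, int(r)).expected_descent
                          for r in ranks])
    return ExtinctionTimes(ranks=ranks, log_ratio=log_ratio, mc_mean=mc_mean,
                           mc_stderr=mc_stderr, predicted=predicted,
                           censored=censored, horizon=horizon)
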