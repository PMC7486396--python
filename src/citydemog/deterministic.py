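"""Deterministic population dynamics: iteration, spectra and fixed points.

In a static environment ``A`` the population evolves as ``N(t) = A**t N(0)``
and converges, for any admissible initial condition, to the leading
eigenvector of ``A`` — an extreme dimensional reduction from ``n`` degrees of
freedom to one.  The approach rate is set by the spectral gap: subdominant
modes decay like ``(|lambda_1|/lambda_0)**t``, giving the characteristic
convergence time ``t* = 1 / ln(lambda_0 / |lambda_1|)``.

Long trajectories are integrated in ``(x, log N_T)`` coordinates — the share
vector plus the log of the total — which is algebraically identical to
iterating the raw sizes but immune to floating-point overflow when the total
population grows exponentially for ``t >> t*``.

The module also covers the self-consistent nonlinear dynamics obtained when
migration flows are bilinear in origin and destination populations: each
city then grows as ``N_i(t+1) = [1 + vital_i - drift_i(x)] N_i(t)`` where
``drift_i = (delta @ x)_i`` is the antisymmetric migration drift evaluated at
the *current* structure (a slow nonlinearity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .environments import (
    DemographyError,
    Environment,
    PopulationState,
    as_structure,
)

__all__ = [
    "Trajectory",
    "SpectralSummary",
    "iterate",
    "spectral_summary",
    "convergence_time",
    "stationary_structure",
    "iterate_self_consistent",
    "solve_self_consistent",
    "self_consistent_residual",
]


@dataclass
class Trajectory:
    """Time-indexed sequence of population structures.

    ``structures[k]`` is the share vector at ``times[k]`` and
    ``log_totals[k]`` the natural log of the total population, so absolute
    sizes are ``structures * exp(log_totals)[:, None]`` whenever that product
    is representable.
    """

    times: np.ndarray
    structures: np.ndarray
    log_totals: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_cities(self) -> int:
        return self.structures.shape[1]

    @property
    def sizes(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return self.structures * np.exp(self.log_totals)[:, np.newaxis]

    def final_state(self) -> PopulationState:
        return PopulationState(self.sizes[-1], time=int(self.times[-1]))

    def final_structure(self) -> np.ndarray:
        return self.structures[-1]


def _normalize_envs(envs, n_steps: int) -> list[Environment]:
    if isinstance(envs, Environment):
        return [envs] * n_steps
    seq = list(envs)
    if len(seq) != n_steps:
        raise DemographyError(f"need {n_steps} environments, got {len(seq)}")
    return seq


def iterate(envs, state0: PopulationState, n_steps: int) -> Trajectory:
    """Iterate ``N(t) = A(t) N(t-1)`` for ``n_steps`` steps.

    ``envs`` may be a single static :class:`Environment` or a sequence of
    length ``n_steps`` (one matrix per step).
    """
    if n_steps < 1:
        raise DemographyError("n_steps must be >= 1")
    seq = _normalize_envs(envs, n_steps)
    n = state0.n_cities
    x = state0.structure.copy()
    log_total = float(np.log(state0.total))
    structures = np.empty((n_steps + 1, n))
    log_totals = np.empty(n_steps + 1)
    structures[0], log_totals[0] = x, log_total
    for t, env in enumerate(seq, start=1):
        if env.n_cities != n:
            raise DemographyError(f"environment at step {t} has wrong dimension")
        y = env.matrix @ x
        s = y.sum()
        if s <= 0:
            raise DemographyError(f"total population vanished at step {t}")
        x = y / s
        log_total += float(np.log(s))
        structures[t], log_totals[t] = x, log_total
    return Trajectory(times=np.arange(n_steps + 1) + state0.time,
                      structures=structures, log_totals=log_totals)


@dataclass
class SpectralSummary:
    """Eigen-decomposition of a static environment.

    Eigenvalues are sorted by descending real part (ties: descending modulus,
    then ascending imaginary part); eigenvectors are the matching columns.
    ``coefficients`` are the projections of the initial population on the
    eigenbasis, so ``sum_i lambda_i**t c_i e_i`` reproduces the iterated
    population.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    coefficients: np.ndarray | None
    condition_number: float

    @property
    def leading_value(self) -> float:
        return float(np.real(self.eigenvalues[0]))

    @property
    def leading_vector(self) -> np.ndarray:
        """Leading eigenvector normalized to the probability simplex."""
        e0 = np.real(self.eigenvectors[:, 0])
        if e0[np.argmax(np.abs(e0))] < 0:
            e0 = -e0
        return e0 / e0.sum()

    @property
    def t_star(self) -> float:
        """Convergence time ``1 / ln(lambda_0 / |lambda_1|)`` in steps."""
        lam0 = self.leading_value
        lam1 = abs(self.eigenvalues[1]) if self.eigenvalues.size > 1 else 0.0
        if lam1 == 0:
            return 0.0
        if np.isclose(lam1, lam0):
            return np.inf
        return 1.0 / np.log(lam0 / lam1)

    def reconstruct(self, t: float) -> np.ndarray:
        """Population at time ``t`` from the spectral expansion."""
        if self.coefficients is None:
            raise DemographyError("no initial population was projected")
        terms = self.eigenvectors @ (self.coefficients * self.eigenvalues**t)
        return np.real(terms)


def spectral_summary(env: Environment, state0: PopulationState | None = None,
                     cond_warn: float = 1e12) -> SpectralSummary:
    """Eigen-decompose an environment and project an initial population."""
    lam, vecs = np.linalg.eig(env.matrix)
    # primary: descending real part; ties: descending modulus, ascending imag
    order = np.lexsort((lam.imag, -np.abs(lam), -lam.real))
    lam, vecs = lam[order], vecs[:, order]
    cond = float(np.linalg.cond(vecs))
    if cond > cond_warn:
        warnings.warn(f"eigenbasis ill-conditioned (condition number {cond:.3g}); "
                      "spectral reconstruction may be inaccurate", stacklevel=2)
    coeffs = None
    if state0 is not None:
        if state0.n_cities != env.n_cities:
            raise DemographyError("environment and state dimensions disagree")
        coeffs = np.linalg.solve(vecs, state0.sizes.astype(complex))
    return SpectralSummary(eigenvalues=lam, eigenvectors=vecs,
                           coefficients=coeffs, condition_number=cond)


def convergence_time(env: Environment) -> float:
    """Spectral-gap convergence time ``t*`` of a static environment."""
    return spectral_summary(env).t_star


def stationary_structure(env: Environment) -> np.ndarray:
    """Stationary share vector: the simplex-normalized leading eigenvector."""
    return spectral_summary(env).leading_vector


def self_consistent_residual(vital, delta, x) -> np.ndarray:
    """Residual of the structural fixed-point condition.

    At a self-consistent structure the centred vital rate of every city is
    balanced by its antisymmetric migration drift:
    ``vital_i - mean(vital) = (delta @ x)_i`` with the mean taken under ``x``.
    Returns the per-city residual vector.
    """
    v = np.asarray(vital, dtype=float)
    d = np.asarray(delta, dtype=float)
    x = np.asarray(x, dtype=float)
    return v - float(v @ x) - d @ x


def iterate_self_consistent(vital, delta, state0: PopulationState,
                            n_steps: int) -> Trajectory:
    """Iterate the nonlinear dynamics ``N_i' = [1 + vital_i - (delta@x)_i] N_i``.

    ``delta`` must be antisymmetric; the migration drift is re-evaluated from
    the current structure at every step, which conserves the total population
    exactly when all vital rates vanish.

    Raises with the offending step index if a growth factor becomes
    non-positive.
    """
    v = np.asarray(vital, dtype=float)
    d = np.asarray(delta, dtype=float)
    if not np.allclose(d, -d.T, atol=1e-10):
        raise DemographyError("delta must be antisymmetric")
    if n_steps < 1:
        raise DemographyError("n_steps must be >= 1")
    n = state0.n_cities
    x = state0.structure.copy()
    log_total = float(np.log(state0.total))
    structures = np.empty((n_steps + 1, n))
    log_totals = np.empty(n_steps + 1)
    structures[0], log_totals[0] = x, log_total
    for t in range(1, n_steps + 1):
        growth = 1.0 + v - d @ x
        if np.any(growth <= 0):
            raise DemographyError(f"non-positive growth factor at step {t}")
        y = growth * x
        s = y.sum()
        x = y / s
        log_total += float(np.log(s))
        structures[t], log_totals[t] = x, log_total
    return Trajectory(times=np.arange(n_steps + 1) + state0.time,
                      structures=structures, log_totals=log_totals)


def solve_self_consistent(vital, delta, x0=None, damping: float = 0.5,
                          tol: float = 1e-12, max_iter: int = 200_000):
    """Solve for a self-consistent stationary structure.

    The fixed-point condition ``vital - mean(vital) = delta @ x`` with the
    mean taken under ``x`` is linear in ``x``; it is solved together with
    the simplex normalization by least squares.  When the linear solution
    leaves the simplex (no interior fixed point exists — e.g. the drift
    overwhelms the vital-rate differences and a city is driven out) a
    damped iteration of the physical dynamics,
    ``x <- (1 - eta) x + eta * normalize(growth * x)`` with
    ``growth = 1 + vital - mean(vital) - delta @ x``, relaxes to the
    attracting (possibly boundary) structure.  Returns ``(x, residual)``
    where ``residual`` is the sup-norm of :func:`self_consistent_residual`
    restricted to the support of ``x``.  Warns instead of raising when the
    iteration stalls, reporting the residual reached; purely rotational
    drift fields (cycling dynamics with no attractor) are the known
    failure mode.
    """
    v = np.asarray(vital, dtype=float)
    d = np.asarray(delta, dtype=float)
    if not np.allclose(d, -d.T, atol=1e-10):
        raise DemographyError("delta must be antisymmetric")
    n = v.size
    ones = np.ones(n)
    a = np.vstack([np.outer(ones, v) + d, ones])
    b = np.concatenate([v, [1.0]])
    x_lin = np.linalg.lstsq(a, b, rcond=None)[0]
    if np.all(x_lin >= -1e-10):
        x_lin = np.clip(x_lin, 0.0, None)
        s = x_lin.sum()
        if s > 0:
            x_lin = x_lin / s
            res = self_consistent_residual(v, d, x_lin)
            support = x_lin > 1e-12
            residual = float(np.max(np.abs(res[support])))
            if residual < 1e-8:
                return x_lin, residual
    x = np.full(n, 1.0 / n) if x0 is None else as_structure(x0)
    eta = damping
    for _ in range(max_iter):
        growth = 1.0 + v - float(v @ x) - d @ x
        y = np.clip(growth, 0.0, None) * x
        s = y.sum()
        if s <= 0:
            raise DemographyError("iteration left the admissible region")
        x_new = (1.0 - eta) * x + eta * (y / s)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    res = self_consistent_residual(v, d, x)
    support = x > 1e-8  # effectively extinct cities drop out of the balance
    residual = float(np.max(np.abs(res[support]))) if support.any() else np.inf
    if residual > 1e-8:
        warnings.warn(f"self-consistent solver did not converge: residual {residual:.3g}",
                      stacklevel=2)
    return x, residual
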