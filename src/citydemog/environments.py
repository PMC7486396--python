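"""Demographic environments for systems of cities.

A system of ``n`` cities exchanging people through migration, while each city
gains and loses residents through births and deaths, is a matrix population
model.  The projection matrix of that model — called the *environment* in
population dynamics — has

* diagonal entries ``1 + vital_i - out_i`` (retention of city ``i``:
  one plus its per-capita vital rate minus its total out-migration
  probability), and
* off-diagonal entries ``A[i, j] = m[j, i]`` — the probability that a
  resident of city ``j`` moves to city ``i`` in one time step.

**Orientation.** Rows index the *destination* and columns the *origin*, so a
population column vector is projected forward as ``N(t) = A N(t-1)``.  Most
published origin/destination migration tables are origin-major, i.e. the
*transpose* of this convention; :class:`MigrationModel` stores the
origin-major probability matrix ``m`` and :func:`build_environment` performs
the transposition.

Time is discrete with a unit step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "DemographyError",
    "DemographicRates",
    "MigrationModel",
    "Environment",
    "PopulationState",
    "MigrationDecomposition",
    "ValidationReport",
    "build_environment",
    "apply_environment",
    "decompose_migration",
    "compose_migration",
    "gravity_flows",
    "migration_from_flows",
    "validate_system",
    "as_structure",
]

#: entries smaller than this are treated as numerically zero when building
#: the flow graph for connectivity checks
CONNECTIVITY_FLOOR = 1e-15


class DemographyError(ValueError):
    """Invalid demographic input (rates, migration matrix or environment)."""


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise DemographyError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DemographyError(f"{name} must be finite")
    return arr


def as_structure(x, tol: float = 1e-8) -> np.ndarray:
    """Validate and return a population-structure (share) vector.

    Shares must be non-negative and sum to one; the returned copy is
    renormalized so the sum is exactly one up to rounding.
    """
    arr = _as_1d(x, "structure vector")
    if np.any(arr < 0):
        raise DemographyError("structure vector has negative shares")
    total = arr.sum()
    if not np.isclose(total, 1.0, rtol=0, atol=tol):
        raise DemographyError(f"structure vector sums to {total!r}, not 1")
    return arr / total


@dataclass(frozen=True)
class DemographicRates:
    """Per-capita birth and death rates per city, per unit time.

    The *vital rate* is ``birth - death``; migration from outside the system
    (non-urban areas, other countries) may be absorbed into it.
    """

    birth: np.ndarray
    death: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "birth", _as_1d(self.birth, "birth rates"))
        object.__setattr__(self, "death", _as_1d(self.death, "death rates"))
        if self.birth.shape != self.death.shape:
            raise DemographyError("birth and death rate vectors differ in length")

    @classmethod
    def from_vital(cls, vital) -> "DemographicRates":
        """Build rates from net vital rates only (births absorb the net)."""
        v = _as_1d(vital, "vital rates")
        return cls(birth=np.maximum(v, 0.0), death=np.maximum(-v, 0.0))

    @property
    def vital(self) -> np.ndarray:
        return self.birth - self.death

    @property
    def n_cities(self) -> int:
        return self.birth.size


@dataclass(frozen=True)
class MigrationModel:
    """Origin-major migration probabilities between cities.

    ``prob[i, j]`` is the probability that a resident of city ``i`` moves to
    city ``j`` during one time step.  The diagonal is zero and every row sum
    (the total out-migration probability of a city) must not exceed one.
    Optionally carries pairwise distances and gravity-law parameters.
    """

    prob: np.ndarray
    distance: np.ndarray | None = None
    gravity_constant: float | None = None
    gravity_exponent: float | None = None

    def __post_init__(self):
        m = np.asarray(self.prob, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DemographyError(f"migration matrix must be square, got {m.shape}")
        if np.any(~np.isfinite(m)):
            raise DemographyError("invalid migration: non-finite probabilities")
        if np.any(m < 0):
            raise DemographyError("invalid migration: negative probabilities")
        if np.any(np.diagonal(m) != 0):
            m = m.copy()
            np.fill_diagonal(m, 0.0)
        if np.any(m.sum(axis=1) > 1 + 1e-12):
            raise DemographyError("invalid migration: out-migration probability exceeds 1")
        object.__setattr__(self, "prob", m)
        if self.distance is not None:
            d = np.asarray(self.distance, dtype=float)
            if d.shape != m.shape:
                raise DemographyError("distance matrix shape mismatch")
            off = ~np.eye(d.shape[0], dtype=bool)
            if np.any(d[off] <= 0):
                raise DemographyError("distances must be positive off the diagonal")
            if not np.allclose(d, d.T):
                raise DemographyError("distance matrix must be symmetric")
            object.__setattr__(self, "distance", d)

    @property
    def n_cities(self) -> int:
        return self.prob.shape[0]

    @property
    def out_rates(self) -> np.ndarray:
        """Total out-migration probability of each city per step."""
        return self.prob.sum(axis=1)


@dataclass
class Environment:
    """Projection matrix of the demographic dynamics (rows = destination)."""

    matrix: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DemographyError(f"environment matrix must be square, got {a.shape}")
        self.matrix = a

    @property
    def n_cities(self) -> int:
        return self.matrix.shape[0]

    def column_sums(self) -> np.ndarray:
        """Per-origin column sums; equal ``1 + vital`` when people are conserved."""
        return self.matrix.sum(axis=0)


@dataclass
class PopulationState:
    """Absolute city populations at one time step."""

    sizes: np.ndarray
    time: int = 0

    def __post_init__(self):
        s = _as_1d(self.sizes, "population sizes")
        if np.any(s < 0):
            raise DemographyError("population sizes must be non-negative")
        if s.sum() <= 0:
            raise DemographyError("total population must be positive")
        self.sizes = s

    @property
    def n_cities(self) -> int:
        return self.sizes.size

    @property
    def total(self) -> float:
        return float(self.sizes.sum())

    @property
    def structure(self) -> np.ndarray:
        """Shares ``x_i = N_i / N_T`` — a probability vector over cities."""
        return self.sizes / self.sizes.sum()


@dataclass(frozen=True)
class MigrationDecomposition:
    """Symmetric/antisymmetric split of migration flows.

    The flow from ``i`` to ``j`` is ``J_ij = ((s_ij + d_ij)/2) x_j N_i`` where
    ``s`` is symmetric (reciprocal exchange) and ``d`` antisymmetric (net
    drift).  Only the antisymmetric part moves relative city sizes.
    """

    symmetric: np.ndarray
    antisymmetric: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.symmetric, dtype=float)
        d = np.asarray(self.antisymmetric, dtype=float)
        if s.shape != d.shape or s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise DemographyError("decomposition matrices must be square and congruent")
        if not np.allclose(s, s.T, atol=1e-10):
            raise DemographyError("symmetric part is not symmetric")
        if not np.allclose(d, -d.T, atol=1e-10):
            raise DemographyError("antisymmetric part is not antisymmetric")
        object.__setattr__(self, "symmetric", s)
        object.__setattr__(self, "antisymmetric", d)

    @property
    def n_cities(self) -> int:
        return self.symmetric.shape[0]


def build_environment(rates: DemographicRates, migration: MigrationModel) -> Environment:
    """Assemble the environment matrix from vital rates and migration.

    Raises
    ------
    DemographyError
        If dimensions disagree or some diagonal entry ``1 + vital - out``
        would be non-positive ("environment not positive").
    """
    if rates.n_cities != migration.n_cities:
        raise DemographyError("rates and migration dimensions disagree")
    diag = 1.0 + rates.vital - migration.out_rates
    if np.any(diag <= 0):
        bad = np.flatnonzero(diag <= 0).tolist()
        raise DemographyError(f"environment not positive: retention <= 0 for cities {bad}")
    a = migration.prob.T.copy()  # rows become destinations
    np.fill_diagonal(a, diag)
    return Environment(a)


def apply_environment(env: Environment, state: PopulationState) -> PopulationState:
    """Project a population one step forward: ``N(t+1) = A N(t)``."""
    if env.n_cities != state.n_cities:
        raise DemographyError("environment and state dimensions disagree")
    return PopulationState(env.matrix @ state.sizes, time=state.time + 1)


def decompose_migration(migration: MigrationModel, x) -> MigrationDecomposition:
    """Split migration probabilities into symmetric and antisymmetric parts.

    Given shares ``x`` the parts are pinned by the two linear relations
    ``s_ij = m_ij/x_j + m_ji/x_i`` and ``d_ij = m_ij/x_j - m_ji/x_i``,
    so that ``m_ij = ((s_ij + d_ij)/2) x_j`` reconstructs the input.
    All shares must be positive.
    """
    x = as_structure(x)
    if x.size != migration.n_cities:
        raise DemographyError("structure vector and migration dimensions disagree")
    if np.any(x <= 0):
        raise DemographyError("degenerate city: zero share in decomposition")
    ratio = migration.prob / x[np.newaxis, :]  # m_ij / x_j
    s = ratio + ratio.T
    d = ratio - ratio.T
    np.fill_diagonal(s, 0.0)
    np.fill_diagonal(d, 0.0)
    return MigrationDecomposition(symmetric=s, antisymmetric=d)


def compose_migration(dec: MigrationDecomposition, x) -> MigrationModel:
    """Rebuild migration probabilities ``m_ij = ((s_ij + d_ij)/2) x_j``."""
    x = as_structure(x)
    if x.size != dec.n_cities:
        raise DemographyError("structure vector and decomposition dimensions disagree")
    m = 0.5 * (dec.symmetric + dec.antisymmetric) * x[np.newaxis, :]
    np.fill_diagonal(m, 0.0)
    if np.any(m < -1e-12):
        raise DemographyError("inconsistent decomposition: negative migration probability")
    m = np.clip(m, 0.0, None)
    return MigrationModel(prob=m)


def gravity_flows(state: PopulationState, distances, gravity_constant: float,
                  gamma: float) -> np.ndarray:
    """Symmetric gravity-law person flows ``J_ij = G N_i N_j / d_ij**gamma``.

    Returns the flow matrix (persons per step, zero diagonal).  The
    equivalent symmetric/antisymmetric decomposition has a vanishing
    antisymmetric part.
    """
    if gravity_constant < 0:
        raise DemographyError("gravity constant must be non-negative")
    d = np.asarray(distances, dtype=float)
    n = state.n_cities
    if d.shape != (n, n):
        raise DemographyError("distance matrix shape mismatch")
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] <= 0):
        raise DemographyError("zero or negative distance off the diagonal")
    j = np.zeros((n, n))
    nn = np.outer(state.sizes, state.sizes)
    j[off] = gravity_constant * nn[off] / d[off] ** gamma
    return j


def migration_from_flows(flows: np.ndarray, state: PopulationState) -> MigrationModel:
    """Convert a person-flow matrix into per-capita migration probabilities.

    ``m_ij = J_ij / N_i`` (flows divided by the origin population).
    """
    f = np.asarray(flows, dtype=float)
    n = state.n_cities
    if f.shape != (n, n):
        raise DemographyError("flow matrix shape mismatch")
    if np.any(state.sizes <= 0):
        raise DemographyError("degenerate city: zero population as flow origin")
    m = f / state.sizes[:, np.newaxis]
    np.fill_diagonal(m, 0.0)
    return MigrationModel(prob=m)


@dataclass
class ValidationReport:
    """Diagnostic checks of the assumptions behind the ergodic theory.

    A system with non-negative entries whose flow graph is strongly connected
    and aperiodic has a unique positive leading eigenvector (the stationary
    structure) to which every initial population converges.
    """

    nonnegative: bool
    strongly_connected: bool
    aperiodic: bool
    failures: list = field(default_factory=list)

    @property
    def primitive(self) -> bool:
        return self.strongly_connected and self.aperiodic

    @property
    def passed(self) -> bool:
        return self.nonnegative and self.primitive


def validate_system(env: Environment, tol: float = CONNECTIVITY_FLOOR) -> ValidationReport:
    """Check positivity, strong connectivity and aperiodicity of an environment.

    Entries below ``tol`` are treated as zero for connectivity purposes.
    Diagnostic only: never raises.
    """
    a = env.matrix
    n = env.n_cities
    failures: list[str] = []
    nonnegative = bool(np.all(a >= -tol))
    if not nonnegative:
        bad = np.argwhere(a < -tol)
        failures.append(f"negative entries at {bad.tolist()}")

    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    dest, orig = np.nonzero(np.abs(a) > tol)
    for i, j in zip(dest.tolist(), orig.tolist()):
        g.add_edge(j, i)  # flow from origin j to destination i

    if n == 1:
        strongly_connected = True
    else:
        strongly_connected = nx.is_strongly_connected(g)
    if not strongly_connected:
        comps = sorted(nx.strongly_connected_components(g), key=len, reverse=True)
        outside = sorted(set(range(n)) - comps[0])
        failures.append(f"cities outside the largest strongly connected component: {outside}")
        aperiodic = False
    else:
        aperiodic = nx.is_aperiodic(g)
        if not aperiodic:
            failures.append("flow graph is periodic (non-primitive environment)")
    return ValidationReport(nonnegative=nonnegative,
                            strongly_connected=strongly_connected,
                            aperiodic=aperiodic, failures=failures)
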