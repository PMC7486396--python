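"""Fokker-Planck analysis of driftless geometric growth of city shares.

The share ``x`` of a city under zero-mean multiplicative noise of volatility
``sigma`` has probability density governed by

    dP/dt = d^2/dx^2 [ (sigma^2 / 2) x^2 P ] = dJ/dx,

with probability current ``J = d/dx [(sigma^2/2) x^2 P]``.  Two stationary
laws exist on an interval ``[x_m, x_M]``:

* **zero current** ``J = 0``: ``P = alpha_1 / x^2`` with
  ``alpha_1 = x_M x_m / (x_M - x_m)`` — the Pareto density equivalent to
  Zipf's rank-size rule with exponent one;
* **constant current** ``J = const``: ``P = c / x`` with
  ``c = 1 / ln(x_M / x_m)`` — a steady probability flux up or down the
  urban hierarchy.

Without boundary conditions the solution from a point mass is lognormal with
log-mean ``ln x_0 - (sigma^2/2)(t - t_0)`` and log-variance
``sigma^2 (t - t_0)``: mass drifts towards ever smaller shares while
spreading.  Current conservation at a lower boundary halts the decay and
selects the 1/x^2 law.

In log coordinates ``y = ln(x/x_0)`` and scaled time
``tau = (sigma^2/2)(t - t_0)`` the equation becomes the constant-coefficient
``dP/dtau = P'' + 3P' + 2P``, whose two stationary modes ``exp(-2y)`` and
``exp(-y)`` are exactly the two laws above, and which factorizes through
``P = exp(-3y/2 - tau/4) g`` into the pure heat equation ``dg/dtau = g''``.

The numerical solver is a conservative finite-volume scheme on a grid
uniform in ``log x`` with geometric-mean cell centres; with zero-current
boundary faces the discrete stationary state is ``alpha_1 / x^2`` at the
cell centres *exactly* (the face-flux telescoping reproduces the continuum
normalization), so the long-time fitted log-log slope is -2 to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.stats import lognorm

from .environments import DemographyError

__all__ = [
    "PowerLawDensity",
    "stationary_zipf_density",
    "stationary_constant_current_density",
    "lognormal_transient",
    "lognormal_transient_dist",
    "LogGrid",
    "DensityEvolution",
    "evolve_density_numeric",
    "matched_current",
    "log_space_operator",
    "EigenExpansion",
    "eigenexpansion",
    "CharacteristicTimes",
    "characteristic_times",
    "RankSizeLaw",
]


@dataclass(frozen=True)
class PowerLawDensity:
    """Truncated power-law density ``coef / x**exponent`` on ``[x_min, x_max]``."""

    exponent: float
    coef: float
    x_min: float
    x_max: float

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        inside = (x >= self.x_min) & (x <= self.x_max)
        out = np.zeros_like(x)
        out[inside] = self.coef / x[inside] ** self.exponent
        return out

    def __call__(self, x) -> np.ndarray:
        return self.pdf(x)


def _check_boundaries(x_m: float, x_M: float):
    if not 0 < x_m < x_M:
        raise DemographyError("boundaries must satisfy 0 < x_m < x_M")


def stationary_zipf_density(x_m: float, x_M: float) -> PowerLawDensity:
    """Zero-current stationary density ``alpha_1 / x**2``.

    ``alpha_1 = x_M x_m / (x_M - x_m)`` normalizes the density on
    ``[x_m, x_M]``; this is the Pareto form of Zipf's law.
    """
    _check_boundaries(x_m, x_M)
    alpha_1 = x_M * x_m / (x_M - x_m)
    return PowerLawDensity(exponent=2.0, coef=alpha_1, x_min=x_m, x_max=x_M)


def stationary_constant_current_density(x_m: float, x_M: float) -> PowerLawDensity:
    """Constant-current stationary density ``c / x`` with ``c = 1/ln(x_M/x_m)``."""
    _check_boundaries(x_m, x_M)
    return PowerLawDensity(exponent=1.0, coef=1.0 / np.log(x_M / x_m),
                           x_min=x_m, x_max=x_M)


def lognormal_transient_dist(t: float, x0: float, t0: float, sigma: float):
    """Frozen lognormal law of the unbounded transient at time ``t``.

    Log-mean ``ln x0 - (sigma^2/2)(t - t0)``, log-variance
    ``sigma^2 (t - t0)``.
    """
    if t <= t0:
        raise DemographyError("need t > t0")
    if sigma <= 0 or x0 <= 0:
        raise DemographyError("sigma and x0 must be positive")
    dt = t - t0
    return lognorm(s=sigma * np.sqrt(dt), scale=x0 * np.exp(-0.5 * sigma**2 * dt))


def lognormal_transient(x, t: float, x0: float, t0: float, sigma: float) -> np.ndarray:
    """Density values of the boundary-free transient (lognormal) at ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DemographyError("x must be positive")
    return lognormal_transient_dist(t, x0, t0, sigma).pdf(x)


@dataclass(frozen=True)
class LogGrid:
    """Finite-volume grid uniform in log share.

    ``faces`` are the cell interfaces, ``centers`` their geometric means —
    the choice that makes the discrete zero-current stationary state the
    exactly normalized ``alpha_1 / x**2``.
    """

    faces: np.ndarray

    @classmethod
    def build(cls, x_m: float, x_M: float, n_cells: int) -> "LogGrid":
        _check_boundaries(x_m, x_M)
        if n_cells < 8:
            raise DemographyError("need at least 8 cells")
        return cls(faces=np.geomspace(x_m, x_M, n_cells + 1))

    @property
    def n_cells(self) -> int:
        return self.faces.size - 1

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.faces[:-1] * self.faces[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.faces)

    def mass(self, p: np.ndarray) -> float:
        return float(np.sum(p * self.widths))


def matched_current(sigma: float, grid: LogGrid) -> float:
    """Boundary flux whose discrete stationary state is the pure 1/x law.

    With this flux imposed at both boundary faces, mass conservation forces
    the 1/x**2 admixture to zero and the evolved density converges to
    ``2 J0 / (sigma^2 x)`` with total mass one.
    """
    xc, w = grid.centers, grid.widths
    return 0.5 * sigma**2 / float(np.sum(w / xc))


@dataclass
class DensityEvolution:
    """Saved states of a finite-volume density evolution."""

    grid: LogGrid
    times: np.ndarray
    densities: np.ndarray   # (n_saves, n_cells)
    mass: np.ndarray

    @property
    def final(self) -> np.ndarray:
        return self.densities[-1]

    def fitted_slope(self, window: tuple | None = None):
        """Log-log slope of the final density vs share (with stderr)."""
        from scipy.stats import linregress
        xc = self.grid.centers
        p = self.final
        sel = slice(None) if window is None else slice(*window)
        mask = p[sel] > 0
        fit = linregress(np.log(xc[sel][mask]), np.log(p[sel][mask]))
        return fit.slope, fit.stderr


def evolve_density_numeric(p0, sigma: float, x_m: float, x_M: float,
                           t_final: float, boundary: str = "zero-current",
                           n_cells: int = 512, dt: float | None = None,
                           theta: float = 1.0, n_saves: int = 2,
                           current: float | None = None) -> DensityEvolution:
    """Integrate the share Fokker-Planck equation on ``[x_m, x_M]``.

    Conservative finite-volume scheme on a log grid; face fluxes are the
    difference quotient of ``q = (sigma^2/2) x^2 P`` between neighbouring
    cell centres.  Time stepping is the theta scheme (``theta=1`` implicit
    Euler, L-stable, the right choice for marching to the stationary state;
    ``theta=0.5`` Crank-Nicolson for transient accuracy).  The implicit
    solve makes the scheme unconditionally stable, so ``dt`` is a pure
    accuracy knob; excessively coarse steps are subdivided automatically.

    ``boundary``:

    * ``"zero-current"`` — reflecting faces, total probability conserved;
      the long-time state is ``alpha_1 / x**2``;
    * ``"constant-current"`` — flux ``current`` (default
      :func:`matched_current`) through both faces; the long-time state is
      the 1/x law;
    * ``"absorbing"`` — ghost cell with zero density below the floor;
      probability leaks out (extinction through the lower boundary).

    ``p0`` may be a callable evaluated at cell centres or an array of cell
    densities; it is renormalized to unit mass.
    """
    if sigma <= 0:
        raise DemographyError("sigma must be positive")
    if boundary not in ("zero-current", "constant-current", "absorbing"):
        raise ValueError("unknown boundary condition")
    grid = LogGrid.build(x_m, x_M, n_cells)
    xc, w = grid.centers, grid.widths
    n = grid.n_cells
    p = np.asarray(p0(xc) if callable(p0) else p0, dtype=float).copy()
    if p.shape != (n,):
        raise DemographyError("p0 has wrong shape for the grid")
    if np.any(p < 0):
        raise DemographyError("initial density must be non-negative")
    p /= grid.mass(p)

    # dP_i/dt = (J_{i+1/2} - J_{i-1/2}) / w_i,  J = (q_right - q_left)/dxc
    coef = 0.5 * sigma**2 * xc**2          # q_i = coef_i * P_i
    dxc = np.diff(xc)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    for i in range(n):
        # flux through the right face of cell i (between centres i, i+1)
        if i < n - 1:
            gr = 1.0 / dxc[i]
            add(i, i + 1, coef[i + 1] * gr / w[i])
            add(i, i, -coef[i] * gr / w[i])
            add(i + 1, i + 1, -coef[i + 1] * gr / w[i + 1])
            add(i + 1, i, coef[i] * gr / w[i + 1])
    source = np.zeros(n)
    if boundary == "constant-current":
        j0 = matched_current(sigma, grid) if current is None else current
        source[-1] += j0 / w[-1]   # inflow through the upper face
        source[0] -= j0 / w[0]     # outflow through the lower face
    elif boundary == "absorbing":
        # ghost value 0 just below the lower face, half spacing
        g0 = 1.0 / (xc[0] - grid.faces[0])
        add(0, 0, -coef[0] * g0 / w[0])
    lop = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))

    if dt is None:
        dt = t_final / 200.0
    n_steps = max(int(np.ceil(t_final / dt)), 1)
    dt = t_final / n_steps
    ident = sparse.identity(n, format="csc")
    solver = splu((ident - theta * dt * lop).tocsc())
    explicit = ident + (1.0 - theta) * dt * lop

    save_at = np.unique(np.linspace(0, n_steps, max(n_saves, 2)).astype(int))
    times, dens, mass = [0.0], [p.copy()], [grid.mass(p)]
    for k in range(1, n_steps + 1):
        rhs = explicit @ p + dt * source
        p = solver.solve(rhs)
        if k in save_at:
            times.append(k * dt)
            dens.append(p.copy())
            mass.append(grid.mass(p))
    return DensityEvolution(grid=grid, times=np.asarray(times),
                            densities=np.asarray(dens), mass=np.asarray(mass))


def log_space_operator(y: np.ndarray):
    """Discretized log-coordinate generator ``P'' + 3 P' + 2 P``.

    Returns a function mapping density samples on the (uniform) grid ``y``
    to the operator applied at the interior points (two cells trimmed at
    each end).  Fourth-order central stencils are used so that, at moderate
    grid spacings where float64 rounding is still negligible, the two
    continuum stationary modes ``exp(-2y)`` (Zipf) and ``exp(-y)``
    (constant current) are annihilated below 1e-8.
    """
    y = np.asarray(y, dtype=float)
    h = np.diff(y)
    if not np.allclose(h, h[0]):
        raise DemographyError("log_space_operator requires a uniform grid")
    h = float(h[0])

    def apply(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        d2 = (-p[4:] + 16 * p[3:-1] - 30 * p[2:-2] + 16 * p[1:-3] - p[:-4]) \
            / (12 * h**2)
        d1 = (-p[4:] + 8 * p[3:-1] - 8 * p[1:-3] + p[:-4]) / (12 * h)
        return d2 + 3.0 * d1 + 2.0 * p[2:-2]

    return apply


@dataclass
class EigenExpansion:
    """Sine-mode expansion of the factorized heat field ``g(y, tau)``.

    With ``basis='dirichlet'`` the modes are the standard heat-equation
    eigenfunctions ``sin(k_n (y - y_m))`` with ``k_n = pi n / L`` decaying as
    ``exp(-k_n^2 tau)``; this satisfies the factorized equation and the
    boundary conditions exactly.  ``basis='printed'`` reproduces the
    variant with ``k_n = 2 pi n / L``, argument shifted by ``-3 tau`` and
    decay ``exp(-(k_n^2 - 2) tau)``, kept for comparison; it spans only the
    odd-about-midpoint part of an initial profile and breaks the boundary
    conditions for ``tau > 0``.
    """

    y_m: float
    y_M: float
    wavenumbers: np.ndarray
    coefficients: np.ndarray
    basis: str = "dirichlet"

    @property
    def length(self) -> float:
        return self.y_M - self.y_m

    def reconstruct(self, y, tau: float = 0.0) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        L = self.length
        norm = np.sqrt(2.0 / L)
        u = y[:, np.newaxis] - self.y_m
        k = self.wavenumbers[np.newaxis, :]
        if self.basis == "dirichlet":
            modes = norm * np.sin(k * u) * np.exp(-self.wavenumbers**2 * tau)
        else:
            modes = norm * np.sin(k * (u - 3.0 * tau)) * \
                np.exp(-(self.wavenumbers**2 - 2.0) * tau)
        return modes @ self.coefficients


def eigenexpansion(y_m: float, y_M: float, g0, n_modes: int = 64,
                   basis: str = "dirichlet", n_quad: int = 4097,
                   boundary_tol: float = 1e-8) -> EigenExpansion:
    """Project an initial profile ``g0`` (vanishing at both ends) on sine modes.

    Coefficients are ``a_n = sqrt(2/L) \\int g0(y) sin(k_n (y - y_m)) dy``
    (Simpson quadrature).  Raises if ``g0`` does not vanish at the
    boundaries.
    """
    from scipy.integrate import simpson

    if y_M <= y_m:
        raise DemographyError("need y_m < y_M")
    if basis not in ("dirichlet", "printed"):
        raise ValueError("basis must be 'dirichlet' or 'printed'")
    L = y_M - y_m
    y = np.linspace(y_m, y_M, n_quad)
    g = np.asarray(g0(y) if callable(g0) else g0, dtype=float)
    if g.shape != y.shape:
        raise DemographyError("g0 samples must match the quadrature grid")
    scale = max(np.max(np.abs(g)), 1.0)
    if abs(g[0]) > boundary_tol * scale or abs(g[-1]) > boundary_tol * scale:
        raise DemographyError("g0 must vanish at both boundaries")
    n = np.arange(1, n_modes + 1)
    k = (np.pi if basis == "dirichlet" else 2.0 * np.pi) * n / L
    norm = np.sqrt(2.0 / L)
    modes = np.sin(np.outer(y - y_m, k))
    a = norm * simpson(g[:, np.newaxis] * modes, x=y, axis=0)
    return EigenExpansion(y_m=y_m, y_M=y_M, wavenumbers=k, coefficients=a,
                          basis=basis)


@dataclass(frozen=True)
class CharacteristicTimes:
    """Stochastic time scales of the share dynamics (steps)."""

    reversal_time: float        # t_r = 1/(2 sigma^2)
    expected_descent: float     # t_r * ln(r_max / r)
    largest_city_time: float    # t_r * ln(r_max)


def characteristic_times(sigma: float, r_max: int, r: int) -> CharacteristicTimes:
    """Growth-reversal time and the descent-time estimate for rank ``r``.

    ``t_r = 1/(2 sigma^2)`` is the time scale on which growth-rate
    fluctuations reverse and Zipf's law emerges; the estimated time for a
    rank-``r`` city to fall through the lower boundary is
    ``t_r ln(r_max/r)`` (an order-of-magnitude scale — see
    :func:`citydemog.stochastic.extinction_times` for the Monte-Carlo mean).
    Doubling ``sigma`` quarters ``t_r``.
    """
    if sigma <= 0:
        raise DemographyError("sigma must be positive")
    if not 1 <= r <= r_max:
        raise DemographyError("rank out of range")
    t_r = 1.0 / (2.0 * sigma**2)
    return CharacteristicTimes(reversal_time=t_r,
                               expected_descent=t_r * float(np.log(r_max / r)),
                               largest_city_time=t_r * float(np.log(r_max)))


@dataclass(frozen=True)
class RankSizeLaw:
    """Rank-size rule ``N(r) = N_0 / r**z``.

    ``rank_at_size`` inverts the rule; for ``z = 1`` it is also the implied
    number of (ghost) cities of a given size demanded by current
    conservation at the lower boundary: a 20-million-person top city implies
    20 million one-person towns, 2 million of ten people, and so on.
    """

    top_size: float
    exponent: float = 1.0

    def __post_init__(self):
        if self.top_size <= 0 or self.exponent <= 0:
            raise DemographyError("top size and exponent must be positive")

    def size_at_rank(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.top_size / r ** self.exponent

    def rank_at_size(self, size) -> np.ndarray:
        size = np.asarray(size, dtype=float)
        return (self.top_size / size) ** (1.0 / self.exponent)

    def relaxation_time(self, sigma: float) -> float:
        return 1.0 / (2.0 * sigma**2)
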