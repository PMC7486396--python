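import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from citydemog import (
    DemographyError,
    RankSizeLaw,
    characteristic_times,
    eigenexpansion,
    evolve_density_numeric,
    lognormal_transient,
    simulate_gbm,
    stationary_constant_current_density,
    stationary_zipf_density,
)
from citydemog.fokker_planck import (
    LogGrid,
    log_space_operator,
    lognormal_transient_dist,
)
from citydemog.diagnostics import kl_divergence


class TestStationaryLaws:
    def test_normalization_constant_half_interval(self):
        law = stationary_zipf_density(0.5, 1.0)
        assert law.coef == pytest.approx(1.0)

    @pytest.mark.parametrize("x_m,x_M", [(1e-4, 1.0), (0.01, 0.5), (1e-3, 0.9)])
    def test_densities_integrate_to_one(self, x_m, x_M):
        for law in (stationary_zipf_density(x_m, x_M),
                    stationary_constant_current_density(x_m, x_M)):
            val, _ = quad(law.pdf, x_m, x_M)
            assert val == pytest.approx(1.0, abs=1e-10)

    def test_current_integral_ratio(self):
        """Vanishing current fixes the density ratio between any two shares
        to the inverse square of the share ratio."""
        law = stationary_zipf_density(1e-3, 1.0)
        x_l, x_u = 0.01, 0.3
        assert law.pdf(np.array([x_u]))[0] / law.pdf(np.array([x_l]))[0] \
            == pytest.approx(x_l**2 / x_u**2)

    def test_constant_current_slope_and_coef(self):
        x_m = 1.0 / np.e
        law = stationary_constant_current_density(x_m, 1.0)
        assert law.coef == pytest.approx(1.0)  # ln ratio = 1
        x = np.geomspace(x_m, 1.0, 50)
        slope = np.polyfit(np.log(x), np.log(law.pdf(x)), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-12)

    def test_two_laws_differ(self):
        grid = LogGrid.build(1e-3, 1.0, 256)
        z = stationary_zipf_density(1e-3, 1.0).pdf(grid.centers) * grid.widths
        c = stationary_constant_current_density(1e-3, 1.0).pdf(grid.centers) * grid.widths
        assert kl_divergence(z / z.sum(), c / c.sum()) > 0.1

    def test_invalid_boundaries(self):
        with pytest.raises(DemographyError):
            stationary_zipf_density(0.5, 0.5)


class TestLognormalTransient:
    def test_integrates_to_one(self):
        val, _ = quad(lambda x: lognormal_transient(np.array([x]), 30.0, 0.5, 0.0, 0.2)[0],
                      1e-12, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_log_mean_drifts_linearly(self):
        for t in (10.0, 50.0, 200.0):
            dist = lognormal_transient_dist(t, 1.0, 0.0, 0.1)
            log_mean = np.log(dist.kwds["scale"])
            assert log_mean == pytest.approx(-0.5 * 0.1**2 * t)

    def test_matches_gbm_histogram(self):
        """Monte-Carlo driftless geometric growth follows the closed-form
        lognormal (Kolmogorov-Smirnov distance below 0.02 at 1e4 paths)."""
        sigma, t = 0.1, 64
        _, paths = simulate_gbm(1.0, sigma, t, 10_000, seed=8)
        dist = lognormal_transient_dist(float(t), 1.0, 0.0, sigma)
        stat = kstest(paths[:, -1], dist.cdf).statistic
        assert stat < 0.02

    def test_requires_forward_time(self):
        with pytest.raises(DemographyError):
            lognormal_transient(np.array([1.0]), 0.0, 1.0, 0.0, 0.1)


class TestNumericEvolution:
    def test_stationary_zipf_is_fixed_point(self):
        sigma = 0.1
        law = stationary_zipf_density(1e-3, 1.0)
        evo = evolve_density_numeric(law.pdf, sigma, 1e-3, 1.0,
                                     t_final=10.0 / sigma**2, n_cells=256)
        assert np.max(np.abs(evo.final - evo.densities[0])) < 1e-8
        assert abs(evo.mass[-1] - 1.0) < 1e-8

    def test_zero_current_converges_to_zipf_law(self):
        sigma = 0.1
        evo = evolve_density_numeric(lambda x: np.ones_like(x), sigma, 1e-4, 1.0,
                                     t_final=40000.0, n_cells=512, dt=200.0)
        slope, _ = evo.fitted_slope()
        assert slope == pytest.approx(-2.0, abs=0.01)
        alpha_1 = stationary_zipf_density(1e-4, 1.0).coef
        coef = np.mean(evo.final * evo.grid.centers**2)
        assert coef == pytest.approx(alpha_1, rel=1e-3)
        assert np.allclose(evo.mass, 1.0, atol=1e-8)

    def test_constant_current_converges_to_one_over_x(self):
        sigma = 0.1
        evo = evolve_density_numeric(lambda x: np.ones_like(x), sigma, 1e-4, 1.0,
                                     t_final=40000.0, n_cells=512, dt=200.0,
                                     boundary="constant-current")
        slope, _ = evo.fitted_slope()
        assert slope == pytest.approx(-1.0, abs=0.01)
        assert abs(evo.mass[-1] - 1.0) < 1e-8

    def test_transient_matches_lognormal(self):
        """Evolving the closed-form transient forward on a wide domain
        reproduces the later closed form (L1 error < 1%)."""
        sigma = 0.2
        t0, t1 = 5.0, 25.0
        p0 = lambda x: lognormal_transient(x, t0, 1.0, 0.0, sigma)
        evo = evolve_density_numeric(p0, sigma, 1e-4, 1e4, t_final=t1 - t0,
                                     n_cells=1024, dt=0.05, theta=0.5)
        target = lognormal_transient(evo.grid.centers, t1, 1.0, 0.0, sigma)
        l1 = np.sum(np.abs(evo.final - target) * evo.grid.widths)
        assert l1 < 0.01

    def test_absorbing_boundary_leaks_mass(self):
        sigma = 0.15
        evo = evolve_density_numeric(lambda x: np.ones_like(x), sigma, 1e-3, 1.0,
                                     t_final=2000.0, n_cells=256,
                                     boundary="absorbing")
        assert evo.mass[-1] < 0.9
        assert np.all(np.diff(evo.mass) <= 1e-12)

    def test_relaxation_timescale(self):
        """A perturbed profile relaxes toward 1/x^2 on the scale of a few
        growth-reversal times 1/(2 sigma^2)."""
        sigma = 0.1
        t_r = 1.0 / (2 * sigma**2)
        law = stationary_zipf_density(1e-3, 1.0)
        p0 = lambda x: law.pdf(x) * (1.0 + 0.5 * np.sin(3 * np.log(x)))
        kl_vals = []
        for t_final in (2 * t_r, 40 * t_r):
            evo = evolve_density_numeric(p0, sigma, 1e-3, 1.0, t_final=t_final,
                                         n_cells=256, dt=t_r / 10)
            p = evo.final * evo.grid.widths
            q = law.pdf(evo.grid.centers) * evo.grid.widths
            kl_vals.append(kl_divergence(p / p.sum(), q / q.sum()))
        assert kl_vals[1] < kl_vals[0] / 100


class TestLogSpaceOperator:
    def test_stationary_modes_annihilated(self):
        """The log-coordinate generator kills exp(-2y) (the Zipf mode) and
        exp(-y) (the constant-current mode) to discretization accuracy."""
        y = np.linspace(0.0, 2.0, 401)
        op = log_space_operator(y)
        for mode in (np.exp(-2.0 * y), np.exp(-y)):
            assert np.max(np.abs(op(mode))) < 1e-8

    def test_non_stationary_mode_not_annihilated(self):
        y = np.linspace(0.0, 2.0, 2001)
        op = log_space_operator(y)
        assert np.max(np.abs(op(np.exp(-3.0 * y)))) > 0.1


class TestEigenExpansion:
    def test_single_mode_is_one_hot(self):
        L = 5.0
        k3 = 3 * np.pi / L
        g0 = lambda y: np.sqrt(2.0 / L) * np.sin(k3 * y)
        exp = eigenexpansion(0.0, L, g0, n_modes=16)
        assert exp.coefficients[2] == pytest.approx(1.0, abs=1e-8)
        others = np.delete(exp.coefficients, 2)
        assert np.max(np.abs(others)) < 1e-8

    def test_parseval(self):
        L = 4.0
        g0 = lambda y: y * (L - y) * np.exp(-y)
        exp = eigenexpansion(0.0, L, g0, n_modes=64)
        y = np.linspace(0.0, L, 4097)
        from scipy.integrate import simpson
        norm2 = simpson(g0(y)**2, x=y)
        assert np.sum(exp.coefficients**2) == pytest.approx(norm2, rel=1e-6)

    def test_reconstruction_at_tau_zero(self):
        L = 6.0
        g0 = lambda y: np.sin(np.pi * y / L) * np.exp(-0.3 * y)
        exp = eigenexpansion(0.0, L, g0, n_modes=64)
        y = np.linspace(0.0, L, 500)
        rec = exp.reconstruct(y)
        l2 = np.sqrt(np.trapezoid((rec - g0(y))**2, y) / np.trapezoid(g0(y)**2, y))
        assert l2 < 0.01

    def test_heat_decay_matches_pde(self):
        """A single sine mode decays as exp(-k^2 tau) under the factorized
        heat equation; the expansion reproduces that amplitude."""
        L = 3.0
        k1 = np.pi / L
        g0 = lambda y: np.sin(k1 * y)
        exp = eigenexpansion(0.0, L, g0, n_modes=8)
        y = np.linspace(0.0, L, 200)
        tau = 0.5
        rec = exp.reconstruct(y, tau=tau)
        assert np.allclose(rec, np.sin(k1 * y) * np.exp(-k1**2 * tau), atol=1e-6)

    def test_printed_variant_spans_odd_part_only(self):
        """The variant with wavenumbers 2*pi*n/L represents only the part of
        the profile antisymmetric about the midpoint; a symmetric bump has
        vanishing coefficients."""
        L = 2.0
        g0 = lambda y: np.sin(np.pi * y / L)  # symmetric about L/2
        exp = eigenexpansion(0.0, L, g0, n_modes=32, basis="printed")
        assert np.max(np.abs(exp.coefficients)) < 1e-8

    def test_nonvanishing_boundary_rejected(self):
        with pytest.raises(DemographyError):
            eigenexpansion(0.0, 1.0, lambda y: np.ones_like(y))


class TestCharacteristicTimes:
    def test_reversal_time_value(self):
        ct = characteristic_times(0.1, 100, 1)
        assert ct.reversal_time == pytest.approx(50.0)
        assert ct.expected_descent == pytest.approx(50.0 * np.log(100))

    def test_bottom_rank_is_zero(self):
        assert characteristic_times(0.2, 50, 50).expected_descent == 0.0

    def test_monotone_decreasing_in_rank(self):
        times = [characteristic_times(0.1, 100, r).expected_descent
                 for r in (1, 5, 20, 99)]
        assert all(a > b for a, b in zip(times, times[1:]))

    def test_doubling_sigma_quarters_reversal_time(self):
        a = characteristic_times(0.05, 10, 1).reversal_time
        b = characteristic_times(0.1, 10, 1).reversal_time
        assert a == pytest.approx(4 * b)


class TestRankSizeLaw:
    def test_ghost_city_counts(self):
        law = RankSizeLaw(top_size=20_000_000)
        assert law.rank_at_size(1) == pytest.approx(20_000_000)
        assert law.rank_at_size(10) == pytest.approx(2_000_000)
        assert law.rank_at_size(100) == pytest.approx(200_000)

    def test_size_rank_round_trip(self):
        law = RankSizeLaw(top_size=1e6, exponent=1.3)
        r = np.array([1.0, 7.0, 42.0])
        assert np.allclose(law.rank_at_size(law.size_at_rank(r)), r)
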