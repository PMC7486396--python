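import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from citydemog import (
    DemographicRates,
    DemographyError,
    Environment,
    MigrationModel,
    PopulationState,
    apply_environment,
    build_environment,
    compose_migration,
    decompose_migration,
    gravity_flows,
    migration_from_flows,
    validate_system,
)
from conftest import random_valid_environment


def simplex(n, rng):
    x = rng.random(n) + 0.05
    return x / x.sum()


class TestBuildEnvironment:
    def test_no_demography_gives_identity(self):
        n = 4
        env = build_environment(DemographicRates.from_vital(np.zeros(n)),
                                MigrationModel(np.zeros((n, n))))
        assert np.array_equal(env.matrix, np.eye(n))

    def test_two_city_matrix_and_column_sums(self, two_city_env):
        assert np.allclose(two_city_env.matrix, [[0.9, 0.2], [0.1, 0.8]])
        assert np.allclose(two_city_env.column_sums(), [1.0, 1.0])

    def test_column_sums_equal_one_plus_vital(self):
        rates = DemographicRates.from_vital([0.05, 0.0])
        mig = MigrationModel(np.array([[0.0, 0.1], [0.2, 0.0]]))
        env = build_environment(rates, mig)
        assert np.allclose(env.column_sums(), [1.05, 1.0])

    def test_column_sum_identity_random(self, rng):
        for _ in range(5):
            n = rng.integers(2, 12)
            m = rng.random((n, n)) * 0.4 / (n - 1)
            np.fill_diagonal(m, 0.0)
            vital = 0.05 * rng.standard_normal(n)
            env = build_environment(DemographicRates.from_vital(vital),
                                    MigrationModel(m))
            assert np.allclose(env.column_sums(), 1.0 + vital, atol=1e-12)

    def test_negative_retention_rejected(self):
        rates = DemographicRates.from_vital([-0.5, 0.0])
        mig = MigrationModel(np.array([[0.0, 0.6], [0.1, 0.0]]))
        with pytest.raises(DemographyError, match="not positive"):
            build_environment(rates, mig)

    def test_excess_out_migration_rejected(self):
        with pytest.raises(DemographyError, match="invalid migration"):
            MigrationModel(np.array([[0.0, 1.2], [0.1, 0.0]]))


class TestApplyEnvironment:
    def test_identity_preserves_population(self, rng):
        env = Environment(np.eye(3))
        state = PopulationState(rng.random(3) * 100 + 1)
        out = apply_environment(env, state)
        assert np.allclose(out.sizes, state.sizes)
        assert out.time == state.time + 1

    def test_two_city_hand_product(self, two_city_env, two_city_state):
        out = apply_environment(two_city_env, two_city_state)
        assert np.allclose(out.sizes, [110.0, 90.0])

    def test_matches_explicit_birth_death_flow_balance(self, rng):
        """One projection step equals the explicit per-city balance of
        births, deaths, in-flows and out-flows."""
        for _ in range(5):
            n = int(rng.integers(2, 10))
            m = rng.random((n, n)) * 0.3 / (n - 1)
            np.fill_diagonal(m, 0.0)
            vital = 0.05 * rng.standard_normal(n)
            env = build_environment(DemographicRates.from_vital(vital),
                                    MigrationModel(m))
            sizes = rng.random(n) * 1000 + 1
            flows = m * sizes[:, np.newaxis]  # J_ij = m_ij N_i
            expected = sizes + vital * sizes + flows.sum(axis=0) - flows.sum(axis=1)
            out = apply_environment(env, PopulationState(sizes))
            assert np.allclose(out.sizes, expected, rtol=1e-12)

    def test_symmetric_flows_leave_populations_unchanged(self, rng):
        """Purely symmetric flow decomposition (delta = 0, vital = 0) moves
        equal numbers in both directions, so every city keeps its size."""
        n = 5
        x = simplex(n, rng)
        s = rng.random((n, n)); s = s + s.T; np.fill_diagonal(s, 0.0)
        from citydemog import MigrationDecomposition
        dec = MigrationDecomposition(symmetric=s, antisymmetric=np.zeros((n, n)))
        mig = compose_migration(dec, x)
        env = build_environment(DemographicRates.from_vital(np.zeros(n)), mig)
        state = PopulationState(x * 1e6)
        out = apply_environment(env, state)
        assert np.allclose(out.sizes, state.sizes, rtol=1e-12)

    def test_dimension_mismatch(self, two_city_env):
        with pytest.raises(DemographyError):
            apply_environment(two_city_env, PopulationState(np.ones(3)))


class TestDecomposition:
    def test_two_city_hand_values(self):
        mig = MigrationModel(np.array([[0.0, 0.1], [0.2, 0.0]]))
        dec = decompose_migration(mig, [0.5, 0.5])
        assert dec.symmetric[0, 1] == pytest.approx(0.6)
        assert dec.antisymmetric[0, 1] == pytest.approx(-0.2)

    def test_reciprocal_symmetric_rates_have_zero_delta(self, rng):
        n = 4
        x = simplex(n, rng)
        s = rng.random((n, n)); s = s + s.T; np.fill_diagonal(s, 0.0)
        m = 0.1 * 0.5 * s * x[np.newaxis, :]  # delta = 0 construction
        dec = decompose_migration(MigrationModel(m), x)
        assert np.allclose(dec.antisymmetric, 0.0, atol=1e-12)

    def test_round_trip_and_conservation(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 9))
            x = simplex(n, rng)
            m = rng.random((n, n)) * 0.3 / (n - 1)
            np.fill_diagonal(m, 0.0)
            mig = MigrationModel(m)
            dec = decompose_migration(mig, x)
            # symmetry / antisymmetry
            assert np.allclose(dec.symmetric, dec.symmetric.T)
            assert np.allclose(dec.antisymmetric, -dec.antisymmetric.T)
            # current conservation: quadratic form vanishes identically
            assert abs(x @ dec.antisymmetric @ x) < 1e-12
            # round trip
            back = compose_migration(dec, x)
            assert np.allclose(back.prob, mig.prob, atol=1e-12)

    def test_zero_share_rejected(self):
        mig = MigrationModel(np.array([[0.0, 0.1], [0.2, 0.0]]))
        with pytest.raises(DemographyError):
            decompose_migration(mig, [1.0, 0.0])

    def test_compose_uniform_constant(self):
        n = 4
        from citydemog import MigrationDecomposition
        c = 0.8
        s = np.full((n, n), c); np.fill_diagonal(s, 0.0)
        dec = MigrationDecomposition(symmetric=s, antisymmetric=np.zeros((n, n)))
        mig = compose_migration(dec, np.full(n, 1.0 / n))
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(mig.prob[off], c / (2 * n))

    def test_inconsistent_decomposition_rejected(self):
        from citydemog import MigrationDecomposition
        n = 2
        d = np.array([[0.0, 5.0], [-5.0, 0.0]])
        s = np.zeros((n, n))
        dec = MigrationDecomposition(symmetric=s, antisymmetric=d)
        with pytest.raises(DemographyError, match="inconsistent"):
            compose_migration(dec, [0.5, 0.5])


class TestGravity:
    def test_zero_constant_gives_zero_flows(self, rng):
        state = PopulationState(rng.random(3) * 100 + 1)
        d = np.ones((3, 3)); np.fill_diagonal(d, 0.0)
        assert np.all(gravity_flows(state, d + 1, 0.0, 1.0) == 0)

    def test_direct_formula_value(self):
        state = PopulationState([1000.0, 2000.0])
        d = np.array([[0.0, 10.0], [10.0, 0.0]])
        j = gravity_flows(state, d, 0.001, 1.0)
        assert j[0, 1] == pytest.approx(200.0)
        assert j[1, 0] == pytest.approx(200.0)

    def test_distance_free_limit(self, rng):
        state = PopulationState(rng.random(4) * 100 + 1)
        d = rng.random((4, 4)) + 0.5
        d = (d + d.T) / 2; np.fill_diagonal(d, 0.0)
        j = gravity_flows(state, d, 0.01, 0.0)
        off = ~np.eye(4, dtype=bool)
        nn = np.outer(state.sizes, state.sizes)
        assert np.allclose(j[off], 0.01 * nn[off])

    def test_gravity_rates_decompose_with_zero_delta(self, rng):
        """Gravity flows are symmetric, so the implied migration rates carry
        no antisymmetric drift."""
        n = 5
        sizes = rng.random(n) * 1000 + 10
        state = PopulationState(sizes)
        coords = rng.random((n, 2))
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(-1)); np.fill_diagonal(d, 1.0)
        j = gravity_flows(state, d, 1e-6, 1.0)
        assert np.allclose(j, j.T)
        mig = migration_from_flows(j, state)
        dec = decompose_migration(mig, state.structure)
        assert np.allclose(dec.antisymmetric, 0.0, atol=1e-10)

    def test_zero_distance_rejected(self):
        state = PopulationState([1.0, 1.0])
        with pytest.raises(DemographyError):
            gravity_flows(state, np.zeros((2, 2)), 1.0, 1.0)


class TestValidateSystem:
    def test_all_positive_passes(self, rng):
        env = random_valid_environment(rng, 6)
        report = validate_system(env)
        assert report.passed and not report.failures

    def test_block_diagonal_fails_connectivity(self):
        a = np.array([[0.9, 0.2, 0.0, 0.0],
                      [0.1, 0.8, 0.0, 0.0],
                      [0.0, 0.0, 0.9, 0.3],
                      [0.0, 0.0, 0.1, 0.7]])
        report = validate_system(Environment(a))
        assert not report.strongly_connected
        assert not report.passed
        assert any("strongly connected" in f for f in report.failures)

    def test_pure_two_cycle_is_periodic(self):
        report = validate_system(Environment(np.array([[0.0, 1.0], [1.0, 0.0]])))
        assert report.strongly_connected
        assert not report.aperiodic
        assert not report.primitive

    def test_negative_entries_flagged(self):
        report = validate_system(Environment(np.array([[0.9, -0.1], [0.1, 0.8]])))
        assert not report.nonnegative


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=10**6))
def test_column_sum_identity_property(n, seed):
    """Flow conservation: each origin's column of the environment sums to
    one plus its vital rate, for any admissible rates and migration."""
    rng = np.random.default_rng(seed)
    m = rng.random((n, n)) * 0.5 / (n - 1)
    np.fill_diagonal(m, 0.0)
    vital = 0.1 * rng.standard_normal(n)
    env = build_environment(DemographicRates.from_vital(vital), MigrationModel(m))
    assert np.allclose(env.column_sums(), 1.0 + vital, atol=1e-12)
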