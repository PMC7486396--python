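"""Scenario generators and flow-table input/output.

Generators reproduce the simulation protocols used throughout the package:
near-equal or Zipfian initial populations, exchangeable environments with a
little noise, gravity-law environments built from sampled coordinates, and
sparse random migration graphs.  All generators are seeded and
bit-reproducible, and every scenario yields inputs on which the other
modules run without any external data.

The readers handle empirical-style origin/destination flow tables —
header-bearing comma-delimited text with columns ``origin_id,
destination_id, count`` — together with a unit-to-aggregate crosswalk
(e.g. county to metropolitan area).  Aggregation folds intra-aggregate
moves out of migration (a move within an integrated labor market is not a
migration event) and conserves cross-aggregate person-flows exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import zipf_reference
from .environments import (
    DemographicRates,
    DemographyError,
    Environment,
    MigrationModel,
    PopulationState,
    build_environment,
    gravity_flows,
    migration_from_flows,
    validate_system,
)

__all__ = [
    "ScenarioSpec",
    "gen_initial_population",
    "gen_environment",
    "gen_noise_process",
    "draw_antisymmetric_lognormal",
    "FlowTable",
    "read_flow_table",
    "write_flow_table",
    "read_crosswalk",
    "aggregate_flows",
    "flows_to_migration",
    "generate_scenario",
    "write_trajectory",
    "read_trajectory",
]

SCENARIOS = ("fig1a", "fig1b", "fig2a", "fig2b_stochastic", "custom")


@dataclass(frozen=True)
class ScenarioSpec:
    """Named simulation scenario with its generator parameters."""

    name: str = "fig1a"
    n_cities: int = 100
    total_population: float = 1e6
    environment: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise DemographyError(f"unknown scenario {self.name!r}")
        if self.n_cities < 2:
            raise DemographyError("scenarios need at least two cities")


def gen_initial_population(kind: str, n_cities: int, total: float,
                           noise_sd: float = 0.0, seed: int = 0) -> PopulationState:
    """Initial populations: near-equal sizes or a Zipf hierarchy.

    ``kind='equal'`` gives ``total/n`` per city times ``1 + noise`` (Gaussian,
    relative sd ``noise_sd``); ``kind='zipf'`` allots sizes proportional to
    ``1/rank`` scaled to ``total``.
    """
    if total <= 0:
        raise DemographyError("total population must be positive")
    rng = np.random.default_rng(seed)
    if kind == "equal":
        sizes = np.full(n_cities, total / n_cities)
        if noise_sd > 0:
            sizes = sizes * np.abs(1.0 + noise_sd * rng.standard_normal(n_cities))
            sizes *= total / sizes.sum()
    elif kind == "zipf":
        sizes = zipf_reference(n_cities) * total
    else:
        raise ValueError("kind must be 'equal' or 'zipf'")
    return PopulationState(sizes)


def _uniform_noise_env(n, rng, out_total=0.2, noise=0.1, vital=None) -> Environment:
    m0 = out_total / (n - 1)
    m = m0 * (1.0 + noise * (2.0 * rng.random((n, n)) - 1.0))
    np.fill_diagonal(m, 0.0)
    v = np.zeros(n) if vital is None else np.asarray(vital, dtype=float)
    return build_environment(DemographicRates.from_vital(v), MigrationModel(m))


def _gravity_env(n, rng, gamma=1.0, out_target=0.2, sizes=None) -> Environment:
    coords = rng.random((n, 2))
    diff = coords[:, np.newaxis, :] - coords[np.newaxis, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 1.0)
    state = PopulationState(zipf_reference(n) * 1e6 if sizes is None else sizes)
    j = gravity_flows(state, d, gravity_constant=1.0, gamma=gamma)
    m_raw = j / state.sizes[:, np.newaxis]
    np.fill_diagonal(m_raw, 0.0)
    scale = out_target / m_raw.sum(axis=1).max()
    mig = MigrationModel(prob=m_raw * scale, distance=d,
                         gravity_constant=scale, gravity_exponent=gamma)
    return build_environment(DemographicRates.from_vital(np.zeros(n)), mig)


def _random_sparse_env(n, rng, connectivity=0.1, rate_scale=0.02,
                       max_retries=50) -> Environment:
    for _ in range(max_retries):
        mask = rng.random((n, n)) < connectivity
        np.fill_diagonal(mask, False)
        m = np.zeros((n, n))
        m[mask] = rng.lognormal(np.log(rate_scale) - 0.5, 1.0, mask.sum())
        row = m.sum(axis=1)
        over = row > 0.8
        if over.any():  # rescale-and-warn policy folded into regeneration
            m[over] *= (0.8 / row[over])[:, np.newaxis]
        env = build_environment(DemographicRates.from_vital(np.zeros(n)),
                                MigrationModel(m))
        if validate_system(env).passed:
            return env
    raise DemographyError("could not generate a strongly connected sparse environment")


def gen_environment(kind: str, n_cities: int, seed: int = 0, **params) -> Environment:
    """Generate a valid random environment of the requested kind.

    ``uniform_noise``: all migration entries equal plus relative noise
    (params ``out_total``, ``noise``, ``vital``); ``gravity``: flows from the
    gravity law on sampled planar coordinates (params ``gamma``,
    ``out_target``, ``sizes``); ``random_sparse``: Bernoulli edges with
    lognormal magnitudes, regenerated until strongly connected (params
    ``connectivity``, ``rate_scale``).
    """
    rng = np.random.default_rng(seed)
    if kind == "uniform_noise":
        return _uniform_noise_env(n_cities, rng, **params)
    if kind == "gravity":
        return _gravity_env(n_cities, rng, **params)
    if kind == "random_sparse":
        return _random_sparse_env(n_cities, rng, **params)
    raise ValueError("kind must be 'uniform_noise', 'gravity' or 'random_sparse'")


def draw_antisymmetric_lognormal(rng, n: int, log_mean: float,
                                 log_sd: float) -> np.ndarray:
    """One antisymmetric drift matrix: lognormal magnitudes, random signs."""
    iu = np.triu_indices(n, 1)
    mags = rng.lognormal(log_mean, log_sd, iu[0].size)
    signs = np.where(rng.random(iu[0].size) < 0.5, 1.0, -1.0)
    vals = mags * signs
    d = np.zeros((n, n))
    d[iu] = vals
    d[iu[1], iu[0]] = -vals
    return d


def gen_noise_process(n_cities: int, n_steps: int, log_mean: float,
                      log_sd: float, antisymmetric: bool = True, seed: int = 0):
    """Stream of per-step stochastic rates (generator, seeded).

    Antisymmetric mode yields drift matrices with ``delta + delta.T = 0``
    exactly; otherwise yields per-city magnitude vectors.  Signs are
    symmetric about zero, so the construction mean vanishes.
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_steps):
        if antisymmetric:
            yield draw_antisymmetric_lognormal(rng, n_cities, log_mean, log_sd)
        else:
            mags = rng.lognormal(log_mean, log_sd, n_cities)
            signs = np.where(rng.random(n_cities) < 0.5, 1.0, -1.0)
            yield mags * signs


@dataclass
class FlowTable:
    """Origin/destination person counts for one period."""

    table: pd.DataFrame  # columns: origin_id, destination_id, count

    COLUMNS = ("origin_id", "destination_id", "count")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise DemographyError(f"flow table missing columns {missing}")
        if (self.table["count"] < 0).any():
            raise DemographyError("flow counts must be non-negative")

    @property
    def units(self) -> list:
        return sorted(set(self.table["origin_id"]) | set(self.table["destination_id"]))

    @property
    def total(self) -> float:
        return float(self.table["count"].sum())

    def to_matrix(self, units=None) -> tuple[np.ndarray, list]:
        """Square origin-major flow matrix plus the unit ordering."""
        units = self.units if units is None else list(units)
        idx = {u: k for k, u in enumerate(units)}
        m = np.zeros((len(units), len(units)))
        for o, d, c in self.table[list(self.COLUMNS)].itertuples(index=False):
            m[idx[o], idx[d]] += c
        return m, units


def read_flow_table(path) -> FlowTable:
    """Read a delimited flow table; self-flows are dropped with a warning."""
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    ft = FlowTable(df[list(FlowTable.COLUMNS)].copy())
    self_rows = ft.table["origin_id"] == ft.table["destination_id"]
    if self_rows.any():
        import warnings
        warnings.warn(f"dropping {int(self_rows.sum())} self-flow rows", stacklevel=2)
        ft = FlowTable(ft.table[~self_rows].reset_index(drop=True))
    return ft


def write_flow_table(flows, path, units=None):
    """Write a :class:`FlowTable` or a square matrix as delimited text."""
    if isinstance(flows, FlowTable):
        flows.table.to_csv(path, index=False)
        return
    m = np.asarray(flows)
    n = m.shape[0]
    units = [str(k) for k in range(n)] if units is None else list(units)
    rows = [(units[i], units[j], m[i, j])
            for i in range(n) for j in range(n) if i != j and m[i, j] != 0]
    pd.DataFrame(rows, columns=list(FlowTable.COLUMNS)).to_csv(path, index=False)


def read_crosswalk(path) -> dict:
    """Read a unit-to-aggregate crosswalk (columns ``unit_id, aggregate_id``)."""
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if not {"unit_id", "aggregate_id"} <= set(df.columns):
        raise DemographyError("crosswalk needs columns unit_id, aggregate_id")
    return dict(zip(df["unit_id"], df["aggregate_id"]))


def aggregate_flows(flows: FlowTable, crosswalk: dict, strict: bool = True) -> FlowTable:
    """Aggregate unit-level flows to the crosswalk's aggregates.

    Intra-aggregate flows become non-moves and are dropped; cross-aggregate
    counts are summed exactly.  In strict mode an unmapped unit raises,
    naming the unit; otherwise its rows are dropped (count reported via the
    returned table's attrs).
    """
    df = flows.table.copy()
    known = df["origin_id"].isin(crosswalk) & df["destination_id"].isin(crosswalk)
    if strict and not known.all():
        missing = sorted(set(df.loc[~df["origin_id"].isin(crosswalk), "origin_id"])
                         | set(df.loc[~df["destination_id"].isin(crosswalk),
                                      "destination_id"]))
        raise DemographyError(f"units missing from crosswalk: {missing}")
    dropped = int((~known).sum())
    df = df[known].copy()
    df["origin_id"] = df["origin_id"].map(crosswalk)
    df["destination_id"] = df["destination_id"].map(crosswalk)
    df = df[df["origin_id"] != df["destination_id"]]
    out = (df.groupby(["origin_id", "destination_id"], as_index=False)["count"]
             .sum())
    ft = FlowTable(out)
    ft.table.attrs["dropped_rows"] = dropped
    return ft


def flows_to_migration(flows: FlowTable, populations,
                       units=None) -> tuple[MigrationModel, list]:
    """Per-capita migration probabilities ``m_ij = count_ij / N_i``.

    ``populations`` maps unit id to population (or is a
    :class:`PopulationState` aligned with ``units``).  Raises when a unit's
    out-flows exceed its population.  Vital rates are not inferred here:
    the residual growth a flow table cannot explain is the balance of
    births, deaths and external migration, recoverable by comparing
    successive population totals.
    """
    m, units = flows.to_matrix(units)
    if isinstance(populations, PopulationState):
        sizes = populations.sizes
        if sizes.size != len(units):
            raise DemographyError("population state does not cover all aggregates")
    else:
        try:
            sizes = np.array([float(populations[u]) for u in units])
        except KeyError as exc:
            raise DemographyError(f"population missing for unit {exc.args[0]!r}") from exc
    if np.any(sizes <= 0):
        raise DemographyError("populations must be positive")
    out = m.sum(axis=1)
    if np.any(out > sizes):
        bad = [units[k] for k in np.flatnonzero(out > sizes)]
        raise DemographyError(f"out-flows exceed origin population for {bad}")
    return migration_from_flows(m, PopulationState(sizes)), units


def generate_scenario(spec: ScenarioSpec) -> dict:
    """Materialize a scenario: environment(s), initial state(s) and manifest.

    ``fig1a``/``fig1b``: one static uniform-noise environment with near-equal
    (a) or Zipfian (b) initial populations.  ``fig2a``: vital rates plus a
    fixed antisymmetric drift for the self-consistent nonlinear dynamics.
    ``fig2b_stochastic``: a stochastic-run configuration.  ``custom`` uses
    ``spec.environment['kind']`` directly.
    """
    from .stochastic import StochasticConfig

    rng_seed = spec.seed
    out: dict = {"spec": spec}
    if spec.name in ("fig1a", "fig1b"):
        env = gen_environment("uniform_noise", spec.n_cities, seed=rng_seed,
                              **spec.environment)
        kind = "equal" if spec.name == "fig1a" else "zipf"
        state = gen_initial_population(kind, spec.n_cities, spec.total_population,
                                       noise_sd=spec.noise.get("initial_sd", 0.05),
                                       seed=rng_seed + 1)
        out.update(environment=env, initial_state=state)
    elif spec.name == "fig2a":
        rng = np.random.default_rng(rng_seed)
        vital = spec.noise.get("vital_sd", 0.01) * rng.standard_normal(spec.n_cities)
        delta = draw_antisymmetric_lognormal(
            rng, spec.n_cities,
            spec.noise.get("log_mean", float(np.log(0.01) - 0.5)),
            spec.noise.get("log_sd", 1.0))
        state = gen_initial_population("equal", spec.n_cities,
                                       spec.total_population, noise_sd=0.05,
                                       seed=rng_seed + 1)
        out.update(vital=vital, delta=delta, initial_state=state)
    elif spec.name == "fig2b_stochastic":
        cfg = StochasticConfig(n_cities=spec.n_cities, seed=rng_seed,
                               **spec.noise)
        out.update(config=cfg)
    else:  # custom
        params = dict(spec.environment)
        kind = params.pop("kind", "uniform_noise")
        env = gen_environment(kind, spec.n_cities, seed=rng_seed, **params)
        state = gen_initial_population(spec.noise.get("initial", "equal"),
                                       spec.n_cities, spec.total_population,
                                       noise_sd=spec.noise.get("initial_sd", 0.0),
                                       seed=rng_seed + 1)
        out.update(environment=env, initial_state=state)
    out["manifest"] = {
        "scenario": spec.name,
        "n_cities": spec.n_cities,
        "total_population": spec.total_population,
        "seed": spec.seed,
        "environment_params": dict(spec.environment),
        "noise_params": dict(spec.noise),
    }
    return out


def write_trajectory(traj, path):
    """Write a trajectory as one row per (t, city, size, share)."""
    times = np.repeat(traj.times, traj.n_cities)
    cities = np.tile(np.arange(traj.n_cities), traj.times.size)
    if hasattr(traj, "log_totals"):
        sizes = traj.sizes.ravel()
    else:  # structure-only runs carry no absolute sizes
        sizes = np.full(times.size, np.nan)
    pd.DataFrame({"t": times, "city": cities, "size": sizes,
                  "share": traj.structures.ravel()}).to_csv(path, index=False)


def read_trajectory(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a trajectory table back as ``(times, structures)``."""
    df = pd.read_csv(path)
    times = np.sort(df["t"].unique())
    piv = df.pivot(index="t", columns="city", values="share").loc[times]
    return times, piv.to_numpy()
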