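"""Environments, feeding schedules, the generation loop and the
Monte Carlo scenario driver.

One generation is one unit of model time.  Feeding inputs are
instantaneous additions at generation boundaries: the bulk-soil
environment receives a 2 mM cellulose pulse every 100 generations
(generations 0, 100, ..., 400 of a 500-generation run) and nothing
else; the rhizosphere receives 2 mM glucose at every generation, with
amino acids non-limiting.  Within each generation the ODE system is
integrated with the stiff LSODA solver; mutation is applied between
integration segments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .community import (
    Community,
    FunctionalGroup,
    MutationEvent,
    MutationRate,
    apply_mutations,
    generate_community,
)
from .errors import ConfigError, SolverError
from .model_core import (
    BurdenMode,
    DEFAULT_PARAMS,
    LifeStrategy,
    ModelState,
    ParameterTable,
    ResourceState,
    rhs,
)

__all__ = [
    "FeedingSchedule",
    "Environment",
    "Scenario",
    "SimulationResult",
    "ScenarioResult",
    "initial_state",
    "step_generation",
    "run_simulation",
    "run_scenario",
    "replicate_seed_sequence",
]

_SOLVER_RTOL = 1e-6
_SOLVER_ATOL = 1e-9


@dataclass(frozen=True)
class FeedingSchedule:
    """Boundary additions: ``amount`` mM of ``resource`` every ``period`` generations."""

    cellulose_amount: float = 0.0
    cellulose_period: int | None = None
    glucose_amount: float = 0.0
    glucose_period: int | None = None

    def inputs_at(self, gen_index: int) -> tuple[float, float]:
        """(cellulose, glucose) added at the start of generation ``gen_index``."""
        c = g = 0.0
        if self.cellulose_period and gen_index % self.cellulose_period == 0:
            c = self.cellulose_amount
        if self.glucose_period and gen_index % self.glucose_period == 0:
            g = self.glucose_amount
        return c, g


@dataclass(frozen=True)
class Environment:
    mode: str  # "bulk_soil" | "rhizosphere"
    feeding: FeedingSchedule

    def __post_init__(self):
        if self.mode not in ("bulk_soil", "rhizosphere"):
            raise ConfigError(f"unknown environment mode {self.mode!r}")

    @classmethod
    def bulk_soil(cls, cellulose_amount: float = 2.0,
                  cellulose_period: int = 100) -> "Environment":
        return cls(mode="bulk_soil",
                   feeding=FeedingSchedule(cellulose_amount=cellulose_amount,
                                           cellulose_period=cellulose_period))

    @classmethod
    def rhizosphere(cls, glucose_amount: float = 2.0,
                    glucose_period: int = 1) -> "Environment":
        return cls(mode="rhizosphere",
                   feeding=FeedingSchedule(glucose_amount=glucose_amount,
                                           glucose_period=glucose_period))

    @classmethod
    def from_mode(cls, mode: str) -> "Environment":
        if mode == "bulk_soil":
            return cls.bulk_soil()
        if mode == "rhizosphere":
            return cls.rhizosphere()
        raise ConfigError(f"unknown environment mode {mode!r}")


@dataclass(frozen=True)
class Scenario:
    """One (environment x mutation rate) cell of the Monte Carlo grid."""

    environment: Environment
    mutation_rate: MutationRate
    n_replicates: int = 1000
    generations: int = 500
    n_species: int = 20
    seed: int = 0
    burden_mode: BurdenMode = BurdenMode.DEFAULT

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")

    def label(self) -> str:
        return f"{self.environment.mode}_{self.mutation_rate.label}"


@dataclass
class SimulationResult:
    """Full record of one 500-generation simulation."""

    community: Community
    biomass: np.ndarray        # (n_species, generations + 1), ng
    resources: np.ndarray      # (generations + 1, 3): C, G, A in mM
    production: np.ndarray     # (n_species, generations + 1), cumulative gross ng
    shannon_final: float
    mutation_log: list[MutationEvent]
    extinction_log: list[tuple[int, int]]  # (generation, species_id)

    @property
    def cumulative_production(self) -> np.ndarray:
        """Per-species cumulative gross biomass production (ng)."""
        return self.production[:, -1]

    @property
    def total_production(self) -> float:
        return float(self.cumulative_production.sum())


@dataclass
class ScenarioResult:
    scenario: Scenario
    table: pd.DataFrame        # one row per replicate
    failures: list[tuple[int, str]] = field(default_factory=list)


def initial_state(community: Community) -> ModelState:
    """Generation-0 state: empty resource pools, equal starting biomass."""
    return ModelState(resources=ResourceState(0.0, 0.0, 0.0),
                      biomass=community.initial_biomass.copy(),
                      alive=np.ones(community.size, dtype=bool))


def step_generation(state: ModelState, community: Community,
                    environment: Environment, gen_index: int,
                    params: ParameterTable = None) -> ModelState:
    """Advance the system by one generation.

    Applies the scheduled feeding input at the boundary, integrates the
    ODE system over one unit of model time with LSODA, clamps
    negativity overshoot, and applies the irreversible extinction
    cutoff.
    """
    p = params if params is not None else community.params
    arrays = community.packed_arrays()
    alive = state.alive & (state.biomass > 0)

    c_in, g_in = environment.feeding.inputs_at(gen_index)
    r = state.resources
    y0 = np.concatenate(([r.C + c_in, r.G + g_in, r.A],
                         state.biomass, state.production))

    rhizo = environment.mode == "rhizosphere"
    args = (arrays["mu_eff"], arrays["Km_G"], arrays["Km_A"],
            arrays["Vmax_T"], arrays["Vmax_cel"], arrays["Km_cel"],
            arrays["leak_max"], arrays["K_leak"], arrays["m"],
            arrays["cel"], arrays["proto"], alive,
            p.y_CG, p.v_conv, p.G_death, p.K_Bcel, rhizo)

    if alive.any():
        y, info = odeint(rhs, y0, [0.0, 1.0], args=args,
                         rtol=_SOLVER_RTOL, atol=_SOLVER_ATOL,
                         mxstep=10000, full_output=True)
        if info["message"] != "Integration successful.":
            raise SolverError(
                f"LSODA failed at generation {gen_index}: {info['message']}",
                generation=gen_index, state=state)
        y1 = y[-1]
    else:
        y1 = y0  # all-dead community: nothing moves but the feeding inputs

    n = community.size
    y1 = np.maximum(y1, 0.0)
    biomass = y1[3:3 + n]
    production = np.maximum(y1[3 + n:], state.production)  # monotone ledger
    # extinction cutoff: irreversible, prevents solver underflow resurrection
    extinct = alive & (biomass < p.B_ext)
    biomass[extinct | ~alive] = 0.0
    new_alive = alive & ~extinct
    return ModelState(resources=ResourceState(*y1[:3]),
                      biomass=biomass, alive=new_alive,
                      production=production)


def run_simulation(community: Community, environment: Environment,
                   mutation_rate: MutationRate | float = 0.0,
                   generations: int = 500,
                   rng=None,
                   params: ParameterTable = None) -> SimulationResult:
    """Run one community for ``generations`` generations.

    The loop alternates deterministic within-generation integration
    (``step_generation``) with the stochastic mutation engine applied
    at generation boundaries.  Deterministic given the community and
    the mutation RNG.
    """
    from .stats import shannon_index

    p = params if params is not None else community.params
    if rng is None:
        rng = np.random.default_rng(0)
    rate = mutation_rate.rate if isinstance(mutation_rate, MutationRate) else float(mutation_rate)

    n = community.size
    biomass = np.empty((n, generations + 1))
    resources = np.empty((generations + 1, 3))
    production = np.empty((n, generations + 1))

    state = initial_state(community)
    biomass[:, 0] = state.biomass
    resources[0] = state.resources.as_array()
    production[:, 0] = 0.0

    mutation_log: list[MutationEvent] = []
    extinction_log: list[tuple[int, int]] = []

    for gen in range(generations):
        prev_alive = state.alive.copy()
        state = step_generation(state, community, environment, gen, params=p)
        for i in np.nonzero(prev_alive & ~state.alive)[0]:
            extinction_log.append((gen, community.specs[i].id))
        if rate > 0:
            mutation_log.extend(
                apply_mutations(community, rate, rng, generation=gen,
                                alive=state.alive))
        biomass[:, gen + 1] = state.biomass
        resources[gen + 1] = state.resources.as_array()
        production[:, gen + 1] = state.production

    final = state.biomass
    shannon = shannon_index(final) if final.sum() > 0 else 0.0
    return SimulationResult(community=community, biomass=biomass,
                            resources=resources, production=production,
                            shannon_final=shannon,
                            mutation_log=mutation_log,
                            extinction_log=extinction_log)


def replicate_seed_sequence(root_seed: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic, order-insensitive per-replicate seed derivation."""
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(replicate,))


def _summarise(result: SimulationResult, replicate: int, seed: int) -> dict:
    comm = result.community
    cum = result.cumulative_production
    row = {
        "replicate": replicate,
        "seed": seed,
        "cum_biomass_total": float(cum.sum()),
        "shannon_final": result.shannon_final,
        "n_alive_final": int((result.biomass[:, -1] > 0).sum()),
        "n_mutations": len(result.mutation_log),
        "n_extinct": len(result.extinction_log),
    }
    groups = comm.initial_groups
    strategies = comm.strategies()
    for g in FunctionalGroup:
        mask = np.array([x is g for x in groups])
        row[f"cum_biomass_{g.value}"] = float(cum[mask].sum())
        row[f"prop0_{g.value}"] = mask.mean()
    for s in LifeStrategy:
        mask = np.array([x is s for x in strategies])
        row[f"cum_biomass_{s.value}"] = float(cum[mask].sum())
    return row


def run_scenario(scenario: Scenario,
                 params: ParameterTable = DEFAULT_PARAMS) -> ScenarioResult:
    """Monte Carlo over ``n_replicates`` independently drawn communities.

    Each replicate derives its own seed stream from the scenario root
    seed and its index, so replicates are independent, order-insensitive
    and individually re-runnable.  Solver failures are recorded per
    replicate and the scenario continues.
    """
    rows = []
    failures: list[tuple[int, str]] = []
    for rep in range(scenario.n_replicates):
        ss = replicate_seed_sequence(scenario.seed, rep)
        ss_comm, ss_mut = ss.spawn(2)
        community = generate_community(ss_comm, n=scenario.n_species,
                                       params=params,
                                       burden_mode=scenario.burden_mode)
        try:
            result = run_simulation(
                community, scenario.environment, scenario.mutation_rate,
                generations=scenario.generations,
                rng=np.random.default_rng(ss_mut), params=params)
        except SolverError as exc:  # pragma: no cover - defensive
            failures.append((rep, str(exc)))
            continue
        rows.append(_summarise(result, rep, seed=scenario.seed))
    table = pd.DataFrame(rows)
    return ScenarioResult(scenario=scenario, table=table, failures=failures)
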