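"""Deterministic core of the soil-aggregate community model.

The model tracks three shared resource pools inside an implicit soil
aggregate — cellulose ``C`` (a polymeric carbon source), glucose ``G``
(the universal growth substrate) and amino acids ``A`` (an essential
growth factor that auxotrophs cannot synthesise) — together with the
biomass of up to *n* prokaryote "species".  Within one generation the
system evolves deterministically under a set of coupled ODEs:

* cellulolytic species depolymerise cellulose to glucose
  (Michaelis–Menten in ``C``),
* every species takes up glucose through membrane transporters
  (Michaelis–Menten in ``G``),
* prototrophs overproduce and leak amino acids to the shared pool
  (Monod in ``G``: leakage scales with the producer's glucose-driven
  activity), auxotrophs take them up (Michaelis–Menten in ``A``),
* biomass grows at ``mu_max * eps_rel * f_lim`` less a linear
  maintenance cost, where ``f_lim`` is the glucose Monod fraction for
  prototrophs and a Liebig minimum of the glucose and amino-acid
  fractions for auxotrophs,
* when glucose falls to the death threshold ``G_death`` cells starve:
  growth, transporter uptake and leakage are all shut down (a smooth
  activity ramp between ``G_death`` and ``2 * G_death`` keeps the
  right-hand side solver-friendly) and biomass decays at the
  maintenance rate; extracellular cellulase keeps working.

Species carry one of two life strategies — copiotroph (high maximum
growth rate, low transporter affinity) or oligotroph (an order of
magnitude lower maximum growth rate, high transporter affinity) — and
two mutable public-good traits (cellulolytic, prototrophic) whose four
combinations define the functional groups: black queens (both),
cellulolytic auxotrophs, non-cellulolytic prototrophs and cheaters
(neither).  Carrying a trait costs maintenance; the burdens are strictly
ordered black queen > cellulolytic auxotroph > non-cellulolytic
prototroph > cheater, and oligotrophs pay a small surcharge for their
energy-dependent high-affinity transporters (reversible via the
swapped-burden sensitivity mode).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "LifeStrategy",
    "BurdenMode",
    "ResourceState",
    "TraitState",
    "SpeciesSpec",
    "ModelState",
    "StrategyParams",
    "ParameterTable",
    "michaelis_menten_rate",
    "monod_fraction",
    "maintenance_burden",
    "cellulase_flux",
    "uptake_flux",
    "amino_leakage_flux",
    "growth_rate",
    "derivative",
    "pack_state",
    "unpack_state",
    "rhs",
]


class LifeStrategy(str, enum.Enum):
    """Canonical r/K-style life strategies."""

    COPIOTROPH = "copiotroph"
    OLIGOTROPH = "oligotroph"


class BurdenMode(str, enum.Enum):
    """Default: oligotrophs pay the transporter surcharge; swapped reverses it."""

    DEFAULT = "default"
    SWAPPED = "swapped"


@dataclass
class ResourceState:
    """Concentrations of the three shared pools (mM; C in polymer units)."""

    C: float = 0.0
    G: float = 0.0
    A: float = 0.0

    def __post_init__(self):
        if min(self.C, self.G, self.A) < 0:
            raise ParameterError("resource concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.G, self.A], dtype=float)


@dataclass
class TraitState:
    """Mutable public-good traits; flags may only ever flip True -> False."""

    cellulolytic: bool
    prototrophic: bool


@dataclass(frozen=True)
class SpeciesSpec:
    """Immutable kinetic identity of a species.

    Units: rates per generation; concentrations mM; specific fluxes
    mmol per ng biomass per generation; eps ng biomass per mmol glucose.
    """

    id: int
    strategy: LifeStrategy
    mu_max: float
    Km_G: float
    Km_A: float
    Vmax_T: float
    eps: float
    eps_rel: float
    Vmax_cel: float
    Km_cel: float
    leak_max: float
    K_leak: float

    def __post_init__(self):
        for name in ("mu_max", "Km_G", "Km_A", "Vmax_T", "eps", "eps_rel",
                     "Vmax_cel", "Km_cel", "leak_max", "K_leak"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"SpeciesSpec.{name} must be strictly positive")


@dataclass
class ModelState:
    """Within-generation dynamical state.

    ``production`` accumulates the positive part of each species' net
    growth (biomass actually built, after maintenance); it is monotone
    non-decreasing in time.
    """

    resources: ResourceState
    biomass: np.ndarray
    alive: np.ndarray
    production: np.ndarray = field(default=None)

    def __post_init__(self):
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.alive = np.asarray(self.alive, dtype=bool)
        if self.production is None:
            self.production = np.zeros_like(self.biomass)
        else:
            self.production = np.asarray(self.production, dtype=float)
        if np.any(self.biomass < 0):
            raise ParameterError("biomass must be non-negative")
        if np.any(self.biomass[~self.alive] != 0):
            raise ParameterError("dead species must carry zero biomass")


# --------------------------------------------------------------------------
# Default parameter set
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyParams:
    """Per-life-strategy kinetic parameters."""

    mu_max: float        # 1/generation
    Km_G: float          # mM
    Km_A: float          # mM
    Vmax_cel: float      # mmol cellulose / (ng * generation)
    Km_cel: float        # mM
    leak_frac: float     # amino-acid leakage as a fraction of Vmax_T
    K_leak: float        # mM


@dataclass(frozen=True)
class ParameterTable:
    """Full default parameter set of the model.

    ``eps`` (growth yield, ng biomass per mmol glucose) ties transporter
    capacity to growth: ``Vmax_T = mu_max * eps_rel / eps`` so that at
    saturation growth exactly converts uptake at yield ``eps``; the
    carbon ledger (production <= eps * glucose uptake) then holds for
    every species by construction.
    """

    copiotroph: StrategyParams = StrategyParams(
        mu_max=2.0, Km_G=10.0, Km_A=0.2,
        Vmax_cel=0.15, Km_cel=3.0, leak_frac=0.8, K_leak=10.0)
    oligotroph: StrategyParams = StrategyParams(
        mu_max=0.2, Km_G=0.01, Km_A=0.002,
        Vmax_cel=0.15, Km_cel=3.0, leak_frac=0.8, K_leak=0.01)
    eps: float = 8.0          # ng biomass per mmol glucose
    eps_rel: float = 0.5      # growth efficiency factor, dimensionless
    y_CG: float = 100.0       # glucose units released per cellulose polymer unit
    v_conv: float = 1.0       # mM per mmol in the implicit aggregate volume
    G_death: float = 0.01     # mM; below this the growth term is suppressed
    B_ext: float = 1e-3       # ng; extinction cutoff
    K_Bcel: float = 150.0     # ng; biomass half-saturation of cellulase capacity
    # base maintenance burden per functional group (copiotroph), 1/generation
    m_black_queen: float = 0.006
    m_cellulolytic_auxotroph: float = 0.0045
    m_non_cellulolytic_prototroph: float = 0.003
    m_cheater: float = 0.0015
    strategy_increment: float = 0.00075  # surcharge for the high-affinity strategy

    def __post_init__(self):
        for strat in (self.copiotroph, self.oligotroph):
            for name in ("mu_max", "Km_G", "Km_A", "Vmax_cel", "Km_cel",
                         "leak_frac", "K_leak"):
                if getattr(strat, name) <= 0:
                    raise ParameterError(f"StrategyParams.{name} must be positive")
        for name in ("eps", "eps_rel", "y_CG", "v_conv", "G_death", "B_ext",
                     "K_Bcel", "strategy_increment"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"ParameterTable.{name} must be positive")
        if not (self.m_black_queen > self.m_cellulolytic_auxotroph
                > self.m_non_cellulolytic_prototroph > self.m_cheater > 0):
            raise ParameterError(
                "maintenance burdens must be strictly ordered "
                "black queen > cellulolytic auxotroph > "
                "non-cellulolytic prototroph > cheater > 0")
        if not self.oligotroph.Km_G < self.copiotroph.Km_G:
            raise ParameterError("oligotroph transporter Km_G must be below copiotroph")
        if not self.oligotroph.Km_A < self.copiotroph.Km_A:
            raise ParameterError("oligotroph transporter Km_A must be below copiotroph")

    def strategy(self, strategy: LifeStrategy) -> StrategyParams:
        return self.copiotroph if strategy == LifeStrategy.COPIOTROPH else self.oligotroph

    def vmax_T(self, strategy: LifeStrategy) -> float:
        return self.strategy(strategy).mu_max * self.eps_rel / self.eps

    def species_spec(self, species_id: int, strategy: LifeStrategy) -> SpeciesSpec:
        """Build the immutable kinetic identity for one species."""
        sp = self.strategy(strategy)
        vmax_t = self.vmax_T(strategy)
        return SpeciesSpec(
            id=species_id, strategy=strategy,
            mu_max=sp.mu_max, Km_G=sp.Km_G, Km_A=sp.Km_A,
            Vmax_T=vmax_t, eps=self.eps, eps_rel=self.eps_rel,
            Vmax_cel=sp.Vmax_cel, Km_cel=sp.Km_cel,
            leak_max=sp.leak_frac * vmax_t, K_leak=sp.K_leak)

    def burden_base(self, traits: TraitState) -> float:
        if traits.cellulolytic and traits.prototrophic:
            return self.m_black_queen
        if traits.cellulolytic:
            return self.m_cellulolytic_auxotroph
        if traits.prototrophic:
            return self.m_non_cellulolytic_prototroph
        return self.m_cheater


DEFAULT_PARAMS = ParameterTable()


def maintenance_burden(traits: TraitState, strategy: LifeStrategy,
                       params: ParameterTable = DEFAULT_PARAMS,
                       mode: BurdenMode = BurdenMode.DEFAULT) -> float:
    """Specific maintenance cost (1/generation) of a trait/strategy profile.

    In the default mode oligotrophs pay a small surcharge for their
    energy-dependent high-affinity transporters; the swapped sensitivity
    mode charges copiotrophs instead.
    """
    m = params.burden_base(traits)
    mode = BurdenMode(mode)
    surcharged = (LifeStrategy.OLIGOTROPH if mode == BurdenMode.DEFAULT
                  else LifeStrategy.COPIOTROPH)
    if strategy == surcharged:
        m += params.strategy_increment
    return m


# --------------------------------------------------------------------------
# Kinetic primitives
# --------------------------------------------------------------------------

def michaelis_menten_rate(Vmax: float, S: float, Km: float) -> float:
    """Michaelis–Menten rate ``Vmax * S / (Km + S)``."""
    if Km <= 0:
        raise ParameterError("Km must be strictly positive")
    if S < 0:
        raise ParameterError("substrate concentration must be non-negative")
    if Vmax < 0:
        raise ParameterError("Vmax must be non-negative")
    return Vmax * S / (Km + S)


def monod_fraction(S: float, K: float) -> float:
    """Monod saturation fraction ``S / (K + S)`` in [0, 1)."""
    if K <= 0:
        raise ParameterError("K must be strictly positive")
    if S < 0:
        raise ParameterError("substrate concentration must be non-negative")
    return S / (K + S)


# --------------------------------------------------------------------------
# Vectorised right-hand side
# --------------------------------------------------------------------------
#
# State packing: y = [C, G, A, B_1..B_n, P_1..P_n] where P accumulates
# gross production.  The kernel below is numba-compiled when numba is
# importable (it is a tight per-generation inner loop called ~10^5
# times per Monte Carlo scenario); the pure-Python fallback is
# identical code.

def _rhs_impl(y, t, mu_eff, Km_G, Km_A, Vmax_T, Vmax_cel, Km_cel,
              leak_max, K_leak, m, cel, proto, alive,
              y_CG, v_conv, G_death, K_Bcel, rhizosphere):
    n = mu_eff.shape[0]
    dy = np.zeros(3 + 2 * n)
    C = max(y[0], 0.0)
    G = max(y[1], 0.0)
    A = max(y[2], 0.0)

    # metabolic activity: cells starve below the glucose death threshold
    # (no growth, transport or leakage); a linear ramp up to 2*G_death
    # keeps the right-hand side continuous for the stiff solver.
    act = (G - G_death) / G_death
    if act < 0.0:
        act = 0.0
    elif act > 1.0:
        act = 1.0

    dC = 0.0
    dG = 0.0
    dA = 0.0
    for i in range(n):
        if not alive[i]:
            continue
        B = max(y[3 + i], 0.0)
        if B == 0.0:
            continue
        # cellulose depolymerisation (cellulolytic species only);
        # cellulase is constitutive and keeps working through starvation.
        # Enzyme capacity saturates with population biomass (expression
        # is capped), so release depends on producer presence more than
        # producer abundance once populations are established.
        if cel[i] and not rhizosphere:
            flux_c = (Vmax_cel[i] * B / (K_Bcel + B)
                      * C / (Km_cel[i] + C) * v_conv)
            dC -= flux_c
            dG += y_CG * flux_c
        fG = G / (Km_G[i] + G)
        dG -= Vmax_T[i] * B * fG * act * v_conv
        # amino-acid pool dynamics are only tracked in bulk soil
        if not rhizosphere:
            if proto[i]:
                dA += leak_max[i] * B * G / (K_leak[i] + G) * act * v_conv
            else:
                dA -= Vmax_T[i] * B * A / (Km_A[i] + A) * act * v_conv
        f_lim = fG
        if (not proto[i]) and (not rhizosphere):
            fA = A / (Km_A[i] + A)
            if fA < f_lim:
                f_lim = fA
        gross = mu_eff[i] * f_lim * act
        net = gross - m[i]
        dy[3 + i] = net * B
        # cumulative biomass production: positive part of net growth
        dy[3 + n + i] = net * B if net > 0.0 else 0.0
    dy[0] = dC
    dy[1] = dG
    dy[2] = dA if not rhizosphere else 0.0
    return dy


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    rhs = numba.njit(cache=True)(_rhs_impl)
except ImportError:  # pragma: no cover
    rhs = _rhs_impl


def pack_state(state: ModelState) -> np.ndarray:
    r = state.resources
    return np.concatenate(([r.C, r.G, r.A], state.biomass, state.production))


def unpack_state(y: np.ndarray, alive: np.ndarray) -> ModelState:
    n = (y.shape[0] - 3) // 2
    y = np.maximum(y, 0.0)
    biomass = y[3:3 + n].copy()
    biomass[~alive] = 0.0
    return ModelState(
        resources=ResourceState(C=y[0], G=y[1], A=y[2]),
        biomass=biomass, alive=alive.copy(),
        production=y[3 + n:].copy())


def _community_arrays(community, burden_mode=BurdenMode.DEFAULT):
    """Delegate to the community's packed kinetic arrays."""
    return community.packed_arrays(burden_mode)


def derivative(t: float, state: ModelState, community,
               environment_mode: str = "bulk_soil",
               params: ParameterTable = None,
               burden_mode: BurdenMode = BurdenMode.DEFAULT) -> np.ndarray:
    """Full right-hand side dState/dt at time ``t`` (packed layout).

    ``environment_mode`` selects the bulk-soil equation set (all three
    pools) or the rhizosphere set, in which amino acids are
    non-limiting: the A-pool is not evaluated and auxotroph growth uses
    the glucose term only.
    """
    from .errors import ConfigError
    if environment_mode not in ("bulk_soil", "rhizosphere"):
        raise ConfigError(f"unknown environment mode: {environment_mode!r}")
    p = params if params is not None else community.params
    arrays = _community_arrays(community, burden_mode)
    alive = state.alive & arrays["alive"]
    y = pack_state(state)
    return rhs(y, t,
               arrays["mu_eff"], arrays["Km_G"], arrays["Km_A"],
               arrays["Vmax_T"], arrays["Vmax_cel"], arrays["Km_cel"],
               arrays["leak_max"], arrays["K_leak"], arrays["m"],
               arrays["cel"], arrays["proto"], alive,
               p.y_CG, p.v_conv, p.G_death, p.K_Bcel,
               environment_mode == "rhizosphere")


# --------------------------------------------------------------------------
# Scalar diagnostic fluxes (mirror the kernel term by term)
# --------------------------------------------------------------------------

def cellulase_flux(state: ModelState, community,
                   params: ParameterTable = None) -> float:
    """Community cellulose depolymerisation rate (polymer mM/generation)."""
    p = params if params is not None else community.params
    C = state.resources.C
    total = 0.0
    for i, (spec, traits) in enumerate(community):
        if state.alive[i] and traits.cellulolytic and state.biomass[i] > 0:
            B = state.biomass[i]
            total += (michaelis_menten_rate(spec.Vmax_cel, C, spec.Km_cel)
                      * B / (p.K_Bcel + B) * p.v_conv)
    return total


def uptake_flux(species_index: int, resource: str, state: ModelState,
                community) -> float:
    """Specific transporter uptake (mmol per ng per generation) of G or A."""
    spec, traits = community[species_index]
    if resource == "G":
        return michaelis_menten_rate(spec.Vmax_T, state.resources.G, spec.Km_G)
    if resource == "A":
        if traits.prototrophic:
            raise ParameterError(
                "prototrophs synthesise their own amino acids; "
                "A-uptake is only defined for auxotrophs")
        return michaelis_menten_rate(spec.Vmax_T, state.resources.A, spec.Km_A)
    raise ParameterError(f"unknown resource {resource!r}")


def amino_leakage_flux(species_index: int, state: ModelState,
                       community, params: ParameterTable = None) -> float:
    """Amino-acid leakage into the pool (mM/generation); zero for auxotrophs."""
    p = params if params is not None else community.params
    spec, traits = community[species_index]
    if not traits.prototrophic or not state.alive[species_index]:
        return 0.0
    return (spec.leak_max * state.biomass[species_index]
            * monod_fraction(state.resources.G, spec.K_leak) * p.v_conv)


def growth_rate(species_index: int, state: ModelState, community,
                environment_mode: str = "bulk_soil",
                burden_mode: BurdenMode = BurdenMode.DEFAULT,
                params: ParameterTable = None) -> float:
    """Net specific growth rate (1/generation) of one species."""
    p = params if params is not None else community.params
    spec, traits = community[species_index]
    m = maintenance_burden(traits, spec.strategy, p, burden_mode)
    G, A = state.resources.G, state.resources.A
    act = min(max(G / p.G_death - 1.0, 0.0), 1.0)
    if act == 0.0:
        return -m
    f_lim = monod_fraction(G, spec.Km_G)
    if not traits.prototrophic and environment_mode == "bulk_soil":
        f_lim = min(f_lim, monod_fraction(A, spec.Km_A))
    return spec.mu_max * spec.eps_rel * f_lim * act - m
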