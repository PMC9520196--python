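"""Kinetic primitives, maintenance ordering and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from soilcom.errors import ConfigError, ParameterError
from soilcom.model_core import (
    BurdenMode,
    DEFAULT_PARAMS,
    LifeStrategy,
    ModelState,
    ResourceState,
    TraitState,
    amino_leakage_flux,
    cellulase_flux,
    derivative,
    growth_rate,
    maintenance_burden,
    michaelis_menten_rate,
    monod_fraction,
    pack_state,
    rhs,
    uptake_flux,
)
from soilcom.community import FunctionalGroup
from soilcom.runner import Environment, FeedingSchedule, run_simulation

from conftest import build_community

C, O = "copiotroph", "oligotroph"
BQ, CA, NP, CH = ("black_queen", "cellulolytic_auxotroph",
                  "non_cellulolytic_prototroph", "cheater")


# -------------------------------------------------------------------------
# Michaelis-Menten / Monod primitives
# -------------------------------------------------------------------------

@pytest.mark.parametrize("Vmax,S,Km,expected", [
    (1.0, 0.0, 0.5, 0.0),       # zero substrate
    (1.0, 0.5, 0.5, 0.5),       # half-saturation identity
    (2.0, 3.0, 1.0, 1.5),       # direct substitution 2*3/4
])
def test_michaelis_menten_values(Vmax, S, Km, expected):
    assert michaelis_menten_rate(Vmax, S, Km) == pytest.approx(expected)


@pytest.mark.parametrize("S,K,expected", [
    (0.0, 1.0, 0.0),
    (2.5, 2.5, 0.5),
    (9.0, 1.0, 0.9),
])
def test_monod_fraction_values(S, K, expected):
    assert monod_fraction(S, K) == pytest.approx(expected)


@pytest.mark.parametrize("call", [
    lambda: michaelis_menten_rate(1.0, 1.0, 0.0),
    lambda: michaelis_menten_rate(1.0, -0.1, 1.0),
    lambda: michaelis_menten_rate(-1.0, 1.0, 1.0),
    lambda: monod_fraction(1.0, -1.0),
    lambda: monod_fraction(-1.0, 1.0),
])
def test_kinetic_parameter_errors(call):
    with pytest.raises(ParameterError):
        call()


@given(ratio=hst.floats(1e-6, 1e6), Km=hst.floats(1e-6, 1e3))
@settings(max_examples=200, deadline=None)
def test_saturation_monotonicity(ratio, Km):
    """MM terms increase in substrate, decrease in Km, stay in [0, Vmax)."""
    S = ratio * Km
    base = michaelis_menten_rate(1.0, S, Km)
    assert 0.0 <= base < 1.0
    assert michaelis_menten_rate(1.0, 2 * S, Km) > base
    assert michaelis_menten_rate(1.0, S, 2 * Km) < base


# -------------------------------------------------------------------------
# Maintenance burden ordering
# -------------------------------------------------------------------------

@pytest.mark.parametrize("strategy", [LifeStrategy.COPIOTROPH,
                                      LifeStrategy.OLIGOTROPH])
@pytest.mark.parametrize("mode", [BurdenMode.DEFAULT, BurdenMode.SWAPPED])
def test_burden_strictly_ordered_across_groups(strategy, mode):
    """black queen > cellulolytic auxotroph > non-cell. prototroph > cheater."""
    ms = [maintenance_burden(FunctionalGroup(g).traits, strategy,
                             DEFAULT_PARAMS, mode)
          for g in (BQ, CA, NP, CH)]
    assert ms[0] > ms[1] > ms[2] > ms[3] > 0


@pytest.mark.parametrize("group", [BQ, CA, NP, CH])
def test_burden_strategy_increment_and_swap(group):
    traits = FunctionalGroup(group).traits
    m_cop = maintenance_burden(traits, LifeStrategy.COPIOTROPH)
    m_oli = maintenance_burden(traits, LifeStrategy.OLIGOTROPH)
    assert m_oli > m_cop  # default: high-affinity transporters cost extra
    m_cop_sw = maintenance_burden(traits, LifeStrategy.COPIOTROPH,
                                  mode=BurdenMode.SWAPPED)
    m_oli_sw = maintenance_burden(traits, LifeStrategy.OLIGOTROPH,
                                  mode=BurdenMode.SWAPPED)
    assert m_cop_sw > m_oli_sw  # sensitivity mode reverses the surcharge


def test_life_strategy_contrasts():
    """Copiotrophs: 10x the max growth rate; oligotrophs: higher affinity."""
    p = DEFAULT_PARAMS
    assert p.copiotroph.mu_max == pytest.approx(10 * p.oligotroph.mu_max)
    assert p.oligotroph.Km_G < p.copiotroph.Km_G
    assert p.oligotroph.Km_A < p.copiotroph.Km_A


# -------------------------------------------------------------------------
# Flux operations
# -------------------------------------------------------------------------

def _single_state(community, C=0.0, G=0.0, A=0.0, B=1.0):
    n = community.size
    return ModelState(resources=ResourceState(C, G, A),
                      biomass=np.full(n, float(B)),
                      alive=np.ones(n, dtype=bool))


def test_cellulase_flux_zero_cases(make_community):
    no_producers = make_community([(C, CH), (O, NP)])
    state = _single_state(no_producers, C=2.0)
    assert cellulase_flux(state, no_producers) == 0.0
    producers = make_community([(C, BQ)])
    assert cellulase_flux(_single_state(producers, C=0.0), producers) == 0.0


def test_cellulase_flux_hand_value(make_community):
    """One producer at B=100 ng, C = Km_cel: half-saturated in C, with the
    enzyme-capacity factor B/(K_Bcel+B)."""
    comm = make_community([(C, BQ)])
    spec = comm.specs[0]
    p = DEFAULT_PARAMS
    state = _single_state(comm, C=spec.Km_cel, B=100.0)
    expected = 0.5 * spec.Vmax_cel * (100.0 / (p.K_Bcel + 100.0)) * p.v_conv
    assert cellulase_flux(state, comm) == pytest.approx(expected, rel=1e-12)


def test_uptake_flux(make_community):
    comm = make_community([(C, CH), (O, CH)])
    assert uptake_flux(0, "G", _single_state(comm, G=0.0), comm) == 0.0
    cop_spec, oli_spec = comm.specs
    state = _single_state(comm, G=cop_spec.Km_G)
    assert uptake_flux(0, "G", state, comm) == pytest.approx(cop_spec.Vmax_T / 2)
    # at equal low substrate the high-affinity oligotroph transporter is
    # relatively more saturated
    low = _single_state(comm, G=0.005)
    assert (uptake_flux(1, "G", low, comm) / oli_spec.Vmax_T
            > uptake_flux(0, "G", low, comm) / cop_spec.Vmax_T)


def test_uptake_flux_prototroph_contract(make_community):
    comm = make_community([(C, BQ)])
    with pytest.raises(ParameterError):
        uptake_flux(0, "A", _single_state(comm, A=1.0), comm)


def test_amino_leakage_flux(make_community):
    comm = make_community([(C, CH), (O, NP)])
    state = _single_state(comm, G=0.0, B=50.0)
    assert amino_leakage_flux(0, state, comm) == 0.0  # auxotrophs never leak
    assert amino_leakage_flux(1, state, comm) == 0.0  # inactive cells leak nothing
    spec = comm.specs[1]
    state = _single_state(comm, G=spec.K_leak, B=50.0)
    expected = 0.5 * spec.leak_max * 50.0 * DEFAULT_PARAMS.v_conv
    assert amino_leakage_flux(1, state, comm) == pytest.approx(expected)


def test_growth_rate_limits(make_community):
    p = DEFAULT_PARAMS
    comm = make_community([(O, NP), (O, CH)])
    spec = comm.specs[0]
    m = maintenance_burden(comm.traits[0], spec.strategy, p)
    # saturation limit: net -> mu_max * eps_rel - m
    sat = _single_state(comm, G=1e4, A=1e4)
    assert growth_rate(0, sat, comm) == pytest.approx(
        spec.mu_max * spec.eps_rel - m, rel=1e-3)
    # death phase below the glucose threshold
    dead = _single_state(comm, G=0.5 * p.G_death)
    assert growth_rate(0, dead, comm) == pytest.approx(-m)
    # auxotroph with no amino acids decays even at saturating glucose
    m1 = maintenance_burden(comm.traits[1], comm.specs[1].strategy, p)
    starved = _single_state(comm, G=1e4, A=0.0)
    assert growth_rate(1, starved, comm) == pytest.approx(-m1)


# -------------------------------------------------------------------------
# Full right-hand side
# -------------------------------------------------------------------------

def test_derivative_all_dead_is_zero(make_community):
    comm = make_community([(C, BQ), (O, CH)])
    state = ModelState(resources=ResourceState(2.0, 1.0, 0.5),
                       biomass=np.zeros(2), alive=np.zeros(2, dtype=bool))
    dy = derivative(0.0, state, comm)
    assert np.allclose(dy, 0.0)


def test_derivative_unknown_environment(make_community):
    comm = make_community([(C, BQ)])
    state = _single_state(comm, C=2.0)
    with pytest.raises(ConfigError):
        derivative(0.0, state, comm, environment_mode="martian_regolith")


def test_rhizosphere_mode_skips_amino_pool(make_community):
    """Amino acids are non-limiting: dA/dt = 0 and auxotroph growth uses
    the glucose term only."""
    comm = make_community([(C, CH)])
    state = _single_state(comm, G=5.0, A=0.0)
    dy_r = derivative(0.0, state, comm, environment_mode="rhizosphere")
    assert dy_r[2] == 0.0
    assert dy_r[3] > 0  # the cheater grows despite A = 0
    dy_b = derivative(0.0, state, comm, environment_mode="bulk_soil")
    assert dy_b[3] < 0  # in bulk soil A = 0 starves it


def test_derivative_matches_scalar_fluxes(make_community):
    """The vectorised kernel agrees term by term with the diagnostic fluxes."""
    comm = make_community([(C, BQ), (O, CH)])
    state = _single_state(comm, C=1.5, G=0.8, A=0.05, B=30.0)
    dy = derivative(0.0, state, comm)
    p = DEFAULT_PARAMS
    cel = cellulase_flux(state, comm)
    assert dy[0] == pytest.approx(-cel, rel=1e-9)
    uptake_G = sum(uptake_flux(i, "G", state, comm) * state.biomass[i]
                   for i in range(2)) * p.v_conv
    assert dy[1] == pytest.approx(p.y_CG * cel - uptake_G, rel=1e-9)
    leak = amino_leakage_flux(0, state, comm)
    uptake_A = uptake_flux(1, "A", state, comm) * state.biomass[1] * p.v_conv
    assert dy[2] == pytest.approx(leak - uptake_A, rel=1e-9)
    for i in range(2):
        assert dy[3 + i] == pytest.approx(
            growth_rate(i, state, comm) * state.biomass[i], rel=1e-9)


def test_glucose_cellulose_mass_ledger(make_community):
    """Over a bulk-soil run, glucose appears only as y_CG x cellulose
    consumed plus feeding; the pool balance closes on uptake."""
    comm = make_community([(C, BQ), (O, BQ), (O, CH)])
    res = run_simulation(comm, Environment.bulk_soil(), 0.0, generations=120,
                         rng=np.random.default_rng(0))
    p = DEFAULT_PARAMS
    c_added = 2.0 * 2  # pulses at generations 0 and 100
    c_consumed = c_added - res.resources[-1, 0]
    g_supplied = p.y_CG * c_consumed
    g_left = res.resources[-1, 1]
    g_consumed = g_supplied - g_left
    assert g_consumed >= 0
    # carbon accounting: biomass built never exceeds yield on glucose consumed
    assert res.total_production <= p.eps * g_consumed / p.v_conv * (1 + 1e-6)


def test_carbon_accounting_random_runs():
    """Production <= eps * glucose consumed for random communities in both
    environments."""
    from soilcom.community import generate_community

    p = DEFAULT_PARAMS
    for seed, env, pulses in [(3, Environment.bulk_soil(), None),
                              (4, Environment.rhizosphere(), None)]:
        comm = generate_community(seed)
        res = run_simulation(comm, env, 0.0, generations=150,
                             rng=np.random.default_rng(seed))
        if env.mode == "bulk_soil":
            c_consumed = 2.0 * 2 - res.resources[-1, 0]
            g_in = p.y_CG * c_consumed
        else:
            g_in = 2.0 * 150
        g_consumed = g_in - res.resources[-1, 1]
        assert res.total_production <= p.eps * g_consumed / p.v_conv * (1 + 1e-6)


def test_three_phase_growth_curve(make_community):
    """A lone copiotrophic black queen on one cellulose pulse shows
    exponential growth, a stationary phase, then decline once glucose
    falls below the 10 uM death threshold."""
    comm = make_community([(C, BQ)])
    env = Environment(mode="bulk_soil",
                      feeding=FeedingSchedule(cellulose_amount=2.0,
                                              cellulose_period=10**9))
    res = run_simulation(comm, env, 0.0, generations=500,
                         rng=np.random.default_rng(0))
    b = res.biomass[0]
    peak = int(np.argmax(b))
    assert 0 < peak < 500
    assert b[peak] > 10 * b[0]          # grew well beyond the inoculum
    assert b[-1] < 0.9 * b[peak]        # declined after the peak
    g = res.resources[:, 1]
    # end state: glucose exhausted into the starvation zone just above the
    # 10 uM death threshold, biomass decaying at about the maintenance rate
    p = DEFAULT_PARAMS
    assert p.G_death * 0.999 <= g[-1] < 2 * p.G_death
    m = comm.maintenance()[0]
    late_decay = np.log(b[-100] / b[-1]) / 99
    assert 0.5 * m < late_decay < 1.1 * m
    # cumulative production peaks in the right order of magnitude for the
    # per-simulation log10 axis (~10^2-10^4 ng)
    assert 1e2 <= res.total_production <= 1e4


def test_stiff_solver_matches_fixed_step_oracle(make_community):
    """LSODA trajectory over one generation agrees with a fixed-step RK4
    integration at dt = 1e-4 to relative tolerance 1e-4 (2-species system)."""
    from scipy.integrate import odeint

    comm = make_community([(C, BQ), (O, CH)])
    arrays = comm.packed_arrays()
    p = DEFAULT_PARAMS
    state = _single_state(comm, C=2.0, G=0.5, A=0.02, B=5.0)
    y0 = pack_state(state)
    args = (arrays["mu_eff"], arrays["Km_G"], arrays["Km_A"],
            arrays["Vmax_T"], arrays["Vmax_cel"], arrays["Km_cel"],
            arrays["leak_max"], arrays["K_leak"], arrays["m"],
            arrays["cel"], arrays["proto"], arrays["alive"],
            p.y_CG, p.v_conv, p.G_death, p.K_Bcel, False)

    lsoda = odeint(rhs, y0, [0.0, 1.0], args=args, rtol=1e-6, atol=1e-9)[-1]

    dt = 1e-4
    y = y0.copy()
    for _ in range(int(round(1.0 / dt))):
        k1 = rhs(y, 0.0, *args)
        k2 = rhs(y + 0.5 * dt * k1, 0.0, *args)
        k3 = rhs(y + 0.5 * dt * k2, 0.0, *args)
        k4 = rhs(y + dt * k3, 0.0, *args)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    scale = np.abs(y) + 1e-8
    assert np.all(np.abs(lsoda - y) / scale < 1e-4)


def test_non_negativity_of_trajectories():
    from soilcom.community import generate_community

    for seed in (1, 2):
        comm = generate_community(seed)
        res = run_simulation(comm, Environment.bulk_soil(), 4.5e-2,
                             generations=200, rng=np.random.default_rng(seed))
        assert np.all(res.biomass >= 0)
        assert np.all(res.resources >= 0)
        assert np.all(np.diff(res.production, axis=1) >= -1e-9)
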