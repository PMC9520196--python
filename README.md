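# soilcom

Consumer–resource simulation of soil-aggregate prokaryote communities
with public-good traits, loss-of-function mutation and Monte Carlo
scenario analysis.

## The problem

Soil bacteria trade in public goods. Cellulolytic species secrete
cellulase that converts plant-derived cellulose into glucose anyone can
take up; prototrophs overproduce and leak amino acids that auxotrophs
depend on. Genome streamlining constantly produces "cheaters" that have
lost these costly functions and grow more efficiently at everyone
else's expense — the Black Queen dynamic. When too many members stop
contributing, the shared resource base erodes and collective growth
suffers: a microbial Tragedy of the Commons.

`soilcom` simulates 20-species communities assembled at random from
eight profiles — four functional groups (black queen = cellulolytic
prototroph, cellulolytic auxotroph, non-cellulolytic prototroph,
cheater = non-cellulolytic auxotroph) crossed with two life strategies
(copiotroph: high μ_max, low transporter affinity; oligotroph: ten-fold
lower μ_max, high affinity) — and grows them for 500 generations in two
environments:

* **bulk soil** — 2 mM cellulose pulsed every 100 generations, nothing
  else; the community must cooperate to eat;
* **rhizosphere** — 2 mM glucose every generation and amino acids
  non-limiting, emulating root exudation; the public goods are
  redundant.

It is intended for theoretical microbial ecologists who want a fast,
reproducible sandbox for biodiversity–function, cross-feeding and
cheater-load questions.

## The model

Within a generation (one unit of model time) the shared pools —
cellulose *C*, glucose *G*, amino acids *A* (mM) — and the biomass
*B_i* (ng) of each species evolve under stiff ODEs (LSODA):

```
dC/dt = − Σ_cel  V_cel,i · B_i/(K_B + B_i) · C/(K_cel + C)
dG/dt = y_CG · (−dC/dt) − Σ_i V_T,i · B_i · G/(K_G,i + G) · a(G)
dA/dt = Σ_proto λ_i · B_i · G/(K_λ,i + G) · a(G)
        − Σ_auxo V_T,i · B_i · A/(K_A,i + A) · a(G)
dB_i/dt = (μ_max,i · ε_rel · f_lim,i · a(G) − m_i) · B_i
```

with `f_lim = G/(K_G+G)` for prototrophs and the Liebig minimum
`min(G/(K_G+G), A/(K_A+A))` for auxotrophs; in the rhizosphere the
amino-acid terms are dropped (A is non-limiting). `a(G)` is a
starvation switch: below the death threshold `G_death` = 10 μM cells
shut down (growth, transport and leakage stop; only the maintenance
drain `−m_i·B_i` remains), ramping linearly back to full activity at
2·`G_death`. Maintenance burdens are strictly ordered black queen >
cellulolytic auxotroph > non-cellulolytic prototroph > cheater, with a
small surcharge for the oligotroph's energy-dependent high-affinity
transporters (reversible via the swapped-burden sensitivity mode).
Species drop out irreversibly below 10⁻³ ng.

Between generations, each species suffers a loss-of-function mutation
with probability 0 (null), 4.5×10⁻⁴ (low), 4.5×10⁻³ (medium) or
4.5×10⁻² (high) per generation, losing cellulase or amino-acid
production (never regaining either). A scenario is one
environment × mutation-rate cell; the full grid is 8 scenarios at 1,000
Monte Carlo replicates each, every replicate a freshly drawn community.
Tracked outputs per replicate: cumulative biomass production (ng,
time-integral of the positive part of net growth), final Shannon index
H = −Σ p ln p, per-group and per-strategy production, mutation and
extinction logs.

Downstream statistics: logistic nonlinear least squares of biomass on
Shannon diversity, OLS of log₁₀ biomass on functional-group
proportions, Welch's t, Kruskal–Wallis, and 5%/95% quantile bands.

## Worked example

```python
import numpy as np
from soilcom import (Environment, MutationRate, Scenario, run_scenario,
                     fit_logistic, welch_t_test)

bulk = run_scenario(Scenario(environment=Environment.bulk_soil(),
                             mutation_rate=MutationRate.from_label("null"),
                             n_replicates=50, seed=1)).table
rhizo = run_scenario(Scenario(environment=Environment.rhizosphere(),
                              mutation_rate=MutationRate.from_label("null"),
                              n_replicates=50, seed=1)).table
print("bulk   median biomass: %.0f ng, median Shannon: %.2f"
      % (np.median(bulk.cum_biomass_total), np.median(bulk.shannon_final)))
print("rhizo  median biomass: %.0f ng, median Shannon: %.2f"
      % (np.median(rhizo.cum_biomass_total), np.median(rhizo.shannon_final)))
fit = fit_logistic(bulk.shannon_final, bulk.cum_biomass_total)
print("logistic fit: R^2 = %.2f, saturation at Shannon %.2f"
      % (fit.r_squared, fit.saturation))
t, df, p = welch_t_test(rhizo.cum_biomass_total, bulk.cum_biomass_total)
print("rhizosphere > bulk soil: Welch t = %.1f, p = %.2g" % (t, p))
```

prints

```
bulk   median biomass: 6367 ng, median Shannon: 2.39
rhizo  median biomass: 7652 ng, median Shannon: 2.71
logistic fit: R^2 = 0.29, saturation at Shannon 3.26
rhizosphere > bulk soil: Welch t = 16.2, p = 2.5e-21
```

Fifty bulk-soil communities produce a median 6.4 μg of biomass over 500
generations and keep a median Shannon diversity of 2.39 (ln 20 ≈ 3.0
would be 20 perfectly even survivors). Their diversity–function
relation is positive and saturating (more functional repertoires, more
production, with diminishing returns), while the fed rhizosphere
communities sit significantly higher in both biomass and diversity —
cooperation only pays where the environment forces it. In every one of
the 50 bulk-soil replicates the oligotrophs out-produce the
copiotrophs; the reverse (and much more marginal) split holds in the
rhizosphere.

The same runs are available from the shell:

```
soilcom simulate --environment bulk_soil --mutation-rate medium --seed 3 \
    --generations 200 --out results/
# final Shannon: 2.6065  cumulative biomass: 2724.6 ng
soilcom scenario --environment rhizosphere --mutation-rate null \
    --replicates 100 --seed 9 --out results/
soilcom grid --replicates 1000 --seed 0 --out results/   # the full study
soilcom analyze results/*.csv --out results/analysis
```

Every scenario writes a tidy per-replicate CSV plus a JSON manifest
(config, seeds, parameter-table checksum) from which any single
replicate can be re-run in isolation.

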