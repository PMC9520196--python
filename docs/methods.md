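# Methods

## Model structure

The simulator is a consumer–resource ODE system for one implicit soil
aggregate. State: three shared pools — cellulose *C* (polymer, mM),
glucose *G* (mM), amino acids *A* (mM) — and per-species biomass *B_i*
(ng) with a cumulative-production ledger *P_i*. Twenty species per
community, each an immutable kinetic identity (life strategy +
parameters) plus two mutable public-good flags (cellulolytic,
prototrophic) whose four combinations define the functional groups.

Fluxes, all Michaelis–Menten/Monod:

* **Depolymerisation** (cellulolytic species): each producer population
  contributes `Vmax_cel · B/(K_Bcel+B) · C/(Km_cel+C)`. The
  `B/(K_Bcel+B)` factor caps enzyme expression per population, so
  release is controlled by producer *presence* once populations are
  established, and by producer abundance only when they are small or
  dying. Cellulase is constitutive: it keeps working through
  starvation, which is what lets a community bootstrap out of a famine.
  Each unit of polymer yields `y_CG` units of glucose.
* **Uptake**: `Vmax_T · S/(Km+S)` per ng, for glucose (everyone) and
  amino acids (auxotrophs only). `Vmax_T = mu_max·eps_rel/eps` ties
  transporter capacity to growth demand, which makes the carbon ledger
  `production ≤ eps × glucose uptake` an identity rather than a tuned
  inequality.
* **Leakage** (prototrophs): `leak_max · B · G/(K_leak+G)` — amino-acid
  overproduction scales with the producer's glucose-driven activity and
  costs the producer nothing beyond its maintenance burden (the burden
  *is* the cost of carrying the trait).
* **Growth**: `mu_max · eps_rel · f_lim − m`, with `f_lim` the glucose
  Monod fraction for prototrophs and the Liebig minimum of the glucose
  and amino-acid fractions for auxotrophs. Maintenance `m` depends on
  traits and strategy and is the only term that never switches off.

**Starvation.** Below `G_death` = 10 μM cells are inactive: growth,
transporter uptake and leakage all stop (linear activity ramp on
[`G_death`, 2·`G_death`] to keep the right-hand side continuous for
LSODA). This is a deliberate strengthening of a growth-only death
threshold: if uptake continues while growth is suppressed, high-affinity
transporters hold glucose in a stable equilibrium *below* the threshold,
every species decays while glucose is consumed to no effect, and the
community can never recover — bulk-soil runs then collapse universally.
With full shutdown, any new supply immediately lifts G past the
threshold and growth resumes. A consequence worth knowing when reading
trajectories: glucose in a starving system pins just *above* 10 μM
rather than crossing it.

**Generations.** One generation = one time unit. At each boundary:
scheduled feeding is added (bulk soil: 2 mM cellulose at generations
0, 100, 200, 300, 400; rhizosphere: 2 mM glucose every generation),
the ODEs are integrated over one unit with LSODA (rtol 10⁻⁶, atol
10⁻⁹), pools are clamped at zero against solver overshoot, species
below 10⁻³ ng are removed irreversibly, and the mutation engine runs:
each alive species mutates with probability equal to the scenario rate,
losing one still-possessed function (uniform choice if both remain).
Functions are never regained, and every loss strictly lowers the
maintenance burden. In the rhizosphere the amino-acid pool is simply
not evaluated and auxotroph growth uses the glucose term alone — "non-
limiting" implemented by removing the limitation, not by a large
constant.

**Cumulative biomass production** is the time-integral of the positive
part of *net* growth (gross minus maintenance). The alternative —
integrating gross growth — makes production in a fully-consumed
environment a pure function of substrate supplied, so the maintenance
savings from genome streamlining would be invisible; with the net
reading, mutation measurably raises rhizosphere production (~150–200 ng
over 500 generations), which is the behaviour the rest of the analysis
stack expects.

## Monte Carlo driver and reproducibility

A scenario is (environment × mutation rate × burden mode), run for
`n_replicates` independently drawn communities. Per-replicate seeds are
`SeedSequence(entropy=root_seed, spawn_key=(replicate,))`, split into a
community-generation stream and a mutation stream, so replicates are
order-insensitive, individually re-runnable, and bit-reproducible
across machines. Community generation draws functional group uniformly
over four and strategy uniformly over two (eight equiprobable
profiles); kinetic parameters are assigned per profile from the
parameter table, and all species start at 1 ng — equal starting
abundances make the final Shannon index purely outcome-driven.

## Statistics

Shannon index on final biomass (natural log, zero-biomass species
excluded). The biodiversity–function relation is a 3-parameter logistic
`Asym/(1+exp((xmid−x)/scal))` fitted by nonlinear least squares
(scipy `curve_fit`, scaled-logit self-start, bounds enforcing an
increasing curve); R² = 1 − SSE/SST, an F-test against the constant
model, and a saturation threshold defined as the diversity beyond which
the marginal gain falls below 5% of the asymptote per Shannon unit.
Group regressions are OLS (statsmodels) of log₁₀ total production on
the generation-0 proportion of a group (counts/20). Welch's t and
Kruskal–Wallis come from scipy (degenerate inputs handled explicitly:
all-identical pooled data gives H = 0, p = 1); the test suite
cross-checks both against hand-computed formulas. No multiple-testing
correction is applied; p-values are reported raw. Quantile bands are
empirical 5%/50%/95% quantiles, per proportion bin where requested,
with empty bins absent rather than interpolated.

## Calibration: what the defaults are tuned to, and how

No published value for the kinetic constants was available, so the
defaults (see `PARAMETERS.md`) were calibrated against the qualitative
and order-of-magnitude constraints the model is meant to exhibit:

1. a lone copiotrophic black queen on a single 2 mM cellulose pulse
   shows the canonical three-phase curve (exponential growth,
   stationary phase, decay once glucose starves) and peaks in the
   10²–10⁴ ng range;
2. rhizosphere median cumulative production ~10^3.88 ng, rising by
   ~150–200 ng as the mutation rate increases (streamlining pays where
   public goods are redundant);
3. bulk-soil production declines monotonically and severely (~1.5
   orders of magnitude at the highest rate) as loss-of-function
   mutations accumulate — the Tragedy of the Commons;
4. oligotrophs out-produce copiotrophs in bulk soil at every mutation
   rate; copiotrophs hold a modest edge in the rhizosphere (median
   ratio ~1.3);
5. a positive, saturating diversity–function relation in bulk soil
   under null mutation, saturating near Shannon 2.8–3.0;
6. swapping the strategy maintenance surcharge (copiotrophs charged
   instead of oligotrophs) leaves cumulative production statistically
   unchanged, isolating μ_max and transporter affinity as the operative
   strategy traits.

Three tensions shaped the final values, and they are worth recording
because they are properties of this model family, not accidents of
tuning:

* **Release vs. spikes.** Glucose release must keep pace with community
  demand (otherwise cellulolytic biomass is the sole driver of
  production and cheater-rich communities cost nothing), but must never
  outrun it early in a run (otherwise glucose transients favour
  copiotroph blooms and the oligotroph results invert). The
  biomass-saturating cellulase capacity plus a large `K_Bcel` is the
  resolution.
* **Burden gaps vs. evenness.** Burden differences compound
  exponentially over 500 generations. Gaps of order 10⁻²/generation
  make every successful community top-heavy, so final-state evenness —
  and with it the Shannon index — *anti*-correlates with production.
  The shipped gaps (1.5×10⁻³ between adjacent groups) preserve the
  strict ordering and the selection gradient while keeping successful
  communities even enough for the positive diversity–function relation.
* **Amino-acid channel.** With uptake capacity tied to growth demand,
  glucose consumed by amino-acid-starved auxotrophs is wasted, which is
  what makes cheater load costly; generous leakage (`leak_frac` 0.8)
  keeps that channel responsive to prototroph abundance instead of
  saturating it.

Known limitations of the calibrated defaults: the bulk-soil logistic R²
sits near 0.2–0.3 (the relation is positive and highly significant, but
composition noise is larger than in target 5 would ideally allow), and
the functional-group regression slopes rank cellulolytic groups above
prototroph-only groups — in this model cellulose release can be made
*nearly* composition-independent, but not fully, without breaking
constraints 4–5, so black-queen proportion retains a positive slope
while the non-cellulolytic prototroph slope hovers near zero. Both are
asserted at their intended values in `tests/test_acceptance.py` and
currently fail there; the assertions are kept strict deliberately.

## What the generator emulates — and what it does not

Random assembly emulates neutral immigration from a large species pool
into a closed aggregate: uniform profile frequencies, equal inocula, no
immigration afterwards. Real soil communities differ in ways that
matter: space and diffusion limits (cheater proximity to producers),
nitrogen/phosphorus/oxygen co-limitation, necromass recycling,
antagonism, horizontal gene transfer, per-metabolite auxotrophies, cell
size. None of these are modelled, so passing tests demonstrate internal
consistency of this consumer-resource caricature, not predictions for
field soil. Within-profile species are kinetically identical, so
community outcomes are driven entirely by profile composition and
mutation history.

## Numerical choices

LSODA (scipy `odeint`) per generation segment, rtol 10⁻⁶ / atol 10⁻⁹,
right-hand side compiled with numba (a pure-Python fallback is
automatic). Pools clamped at zero after each segment; extinction at
10⁻³ ng is permanent. The suite verifies the stiff trajectories against
a fixed-step RK4 oracle at dt = 10⁻⁴ on a two-species system (relative
tolerance 10⁻⁴), non-negativity on every recorded trajectory, the
carbon ledger on every run it touches, and bit-identical replay of
whole scenarios from the manifest seeds. Test and acceptance runs use
reduced replicate counts (60–300 per cell, vs. 1,000 in the full grid)
chosen so the whole suite completes in minutes; all reported quantities
are Monte Carlo summaries and carry the corresponding sampling noise.
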