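# Default parameter table: values and provenance

All defaults live in `soilcom.model_core.ParameterTable` and can be
overridden from the YAML config (`parameters:` block) or the `--params`
CLI flag. Rates are per generation (one unit of model time);
concentrations mM; biomass ng. The implicit aggregate volume is folded
into the single conversion constant `v_conv` (mM of pool change per
mmol of specific flux), default 1.

## Per-life-strategy kinetics

| parameter | copiotroph | oligotroph | meaning | provenance |
|---|---|---|---|---|
| `mu_max` | 2.0 | 0.2 | maximum specific growth rate (1/gen) | ratio fixed at 10× (copiotrophs an order of magnitude faster); absolute scale calibrated so that oligotroph producers retain a positive net-growth margin over their maintenance burden at saturation |
| `Km_G` | 10.0 | 0.01 | glucose transporter half-saturation (mM) | oligotroph affinity ≫ copiotroph affinity; the 1000× contrast is what lets oligotrophs win the low-glucose trickle between feeding pulses while copiotrophs win glucose-rich transients |
| `Km_A` | 0.2 | 0.002 | amino-acid transporter half-saturation (mM) | same affinity ordering, scaled to the much smaller amino-acid pool |
| `Vmax_cel` | 0.15 | 0.15 | cellulase capacity at enzyme saturation (mmol polymer/gen per population) | calibrated jointly with `K_Bcel` so that established producer populations release a 2 mM pulse over tens of generations — fast enough that release rarely caps community growth, slow enough that glucose never spikes into the copiotroph-favourable range at the start of a run |
| `Km_cel` | 3.0 | 3.0 | cellulase half-saturation in cellulose (mM) | above the 2 mM pulse size, so release is roughly proportional to remaining cellulose |
| `leak_frac` | 0.8 | 0.8 | amino-acid leakage as a fraction of the transporter Vmax | prototrophs are assumed to overproduce generously; lower values starve auxotrophs of amino acids almost regardless of community composition |
| `K_leak` | 10.0 | 0.01 | half-saturation of the glucose-driven leakage Monod (mM) | tied to each strategy's `Km_G`: leakage tracks the producer's own glucose-driven activity |

`Vmax_T` (max specific transporter uptake) is derived, not free:
`Vmax_T = mu_max · eps_rel / eps`, so at saturation growth converts
uptake exactly at yield `eps` and the carbon ledger
(production ≤ eps × glucose uptake) holds by construction.

## Global constants

| parameter | default | meaning | provenance |
|---|---|---|---|
| `eps` | 8.0 ng/mmol | growth yield on glucose | sets the absolute biomass scale; with the rhizosphere's 1,000 mM total glucose input it places rhizosphere median cumulative production at ~10^3.9 ng |
| `eps_rel` | 0.5 | growth efficiency factor | continuous-culture efficiencies are well below 1; 0.5 for all species |
| `y_CG` | 100 | glucose units released per unit of cellulose polymer | cellulose is tracked as polymer; 100 is a modest degree of polymerisation and reconciles the 10 mM total cellulose input with bulk-soil cumulative production of ~10^3.5–10^3.8 ng |
| `v_conv` | 1.0 | mM per mmol in the implicit aggregate volume | volume never appears explicitly; all calibration is done in the combined units |
| `G_death` | 0.01 mM | starvation threshold (10 μM) | growth, uptake and leakage shut down below it (linear ramp to 2×); reproduces the three-phase growth curve of a lone copiotrophic black queen |
| `B_ext` | 10⁻³ ng | extinction cutoff | prevents stiff-solver underflow resurrection |
| `K_Bcel` | 150 ng | biomass half-saturation of cellulase capacity | enzyme expression is capped per population, so cellulose release depends on producer presence more than producer abundance once populations are established |

## Maintenance burdens (1/generation)

| profile | copiotroph | oligotroph |
|---|---|---|
| black queen | 0.006 | 0.00675 |
| cellulolytic auxotroph | 0.0045 | 0.00525 |
| non-cellulolytic prototroph | 0.003 | 0.00375 |
| cheater | 0.0015 | 0.00225 |

Strict ordering black queen > cellulolytic auxotroph >
non-cellulolytic prototroph > cheater; oligotrophs pay the +0.00075
surcharge for energy-dependent high-affinity transporters (the
`swapped` burden mode charges copiotrophs instead). The *gaps* are
deliberately small: burden differences compound exponentially over 500
generations, and wider gaps turn every community top-heavy, which
destroys the positive diversity–function relation and starves
cellulolytic producers at the between-pulse glucose trickle. See
`docs/methods.md` for the full calibration story and the outcomes these
defaults do and do not reproduce.
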