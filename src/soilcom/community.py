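"""Random community assembly and the loss-of-function mutation engine.

Communities hold 20 species by default.  Each species independently
draws one of the four functional groups (uniformly) and one of the two
life strategies (uniformly), giving eight equiprobable profiles.
Kinetic parameters are assigned per profile from the parameter table;
only the two public-good trait flags are mutable, and they may only
ever be lost (no horizontal gene transfer).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .model_core import (
    BurdenMode,
    DEFAULT_PARAMS,
    LifeStrategy,
    ParameterTable,
    SpeciesSpec,
    TraitState,
    maintenance_burden,
)

__all__ = [
    "FunctionalGroup",
    "MutationRate",
    "MUTATION_RATES",
    "MutationEvent",
    "Community",
    "generate_community",
    "classify_functional_group",
    "apply_mutations",
]


class FunctionalGroup(str, enum.Enum):
    BLACK_QUEEN = "black_queen"
    CELLULOLYTIC_AUXOTROPH = "cellulolytic_auxotroph"
    NON_CELLULOLYTIC_PROTOTROPH = "non_cellulolytic_prototroph"
    CHEATER = "cheater"

    @property
    def traits(self) -> TraitState:
        cel = self in (FunctionalGroup.BLACK_QUEEN,
                       FunctionalGroup.CELLULOLYTIC_AUXOTROPH)
        proto = self in (FunctionalGroup.BLACK_QUEEN,
                         FunctionalGroup.NON_CELLULOLYTIC_PROTOTROPH)
        return TraitState(cellulolytic=cel, prototrophic=proto)


def classify_functional_group(traits: TraitState) -> FunctionalGroup:
    """Map the two public-good flags to the four functional groups."""
    if traits.cellulolytic and traits.prototrophic:
        return FunctionalGroup.BLACK_QUEEN
    if traits.cellulolytic:
        return FunctionalGroup.CELLULOLYTIC_AUXOTROPH
    if traits.prototrophic:
        return FunctionalGroup.NON_CELLULOLYTIC_PROTOTROPH
    return FunctionalGroup.CHEATER


# Probability per species per generation of one loss-of-function mutation.
MUTATION_RATES = {
    "null": 0.0,
    "low": 4.5e-4,
    "medium": 4.5e-3,
    "high": 4.5e-2,
}


@dataclass(frozen=True)
class MutationRate:
    label: str
    rate: float

    @classmethod
    def from_label(cls, label: str) -> "MutationRate":
        try:
            return cls(label=label, rate=MUTATION_RATES[label])
        except KeyError:
            raise ParameterError(
                f"unknown mutation rate label {label!r}; "
                f"expected one of {sorted(MUTATION_RATES)}") from None


@dataclass(frozen=True)
class MutationEvent:
    generation: int
    species_id: int
    lost_function: str  # "cellulase" | "amino_acid_production"


class Community:
    """Roster of species: immutable kinetic specs plus mutable traits.

    Maintains packed per-species kinetic arrays for the ODE kernel;
    the arrays are refreshed in place whenever a trait is lost.
    """

    def __init__(self, species, params: ParameterTable = DEFAULT_PARAMS,
                 initial_biomass: float = 1.0,
                 burden_mode: BurdenMode = BurdenMode.DEFAULT):
        if not species:
            raise ParameterError("a community needs at least one species")
        self.specs: list[SpeciesSpec] = [s for s, _ in species]
        self.traits: list[TraitState] = [t for _, t in species]
        self.params = params
        self.burden_mode = BurdenMode(burden_mode)
        self.initial_biomass = np.full(len(self.specs), float(initial_biomass))
        # generation-0 census, retained for reporting even after mutation
        self.initial_groups = [classify_functional_group(t) for t in self.traits]
        self._arrays = self._build_arrays()

    @property
    def size(self) -> int:
        return len(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, i):
        return self.specs[i], self.traits[i]

    def __iter__(self):
        return iter(zip(self.specs, self.traits))

    def functional_groups(self) -> list[FunctionalGroup]:
        """Current (possibly mutated) functional-group census."""
        return [classify_functional_group(t) for t in self.traits]

    def group_counts(self, initial: bool = True) -> dict:
        groups = self.initial_groups if initial else self.functional_groups()
        return {g: sum(1 for x in groups if x is g) for g in FunctionalGroup}

    def strategies(self) -> list[LifeStrategy]:
        return [s.strategy for s in self.specs]

    # -- packed arrays for the ODE kernel ---------------------------------

    def _build_arrays(self) -> dict:
        n = self.size
        arr = {
            "mu_eff": np.array([s.mu_max * s.eps_rel for s in self.specs]),
            "Km_G": np.array([s.Km_G for s in self.specs]),
            "Km_A": np.array([s.Km_A for s in self.specs]),
            "Vmax_T": np.array([s.Vmax_T for s in self.specs]),
            "Vmax_cel": np.array([s.Vmax_cel for s in self.specs]),
            "Km_cel": np.array([s.Km_cel for s in self.specs]),
            "leak_max": np.array([s.leak_max for s in self.specs]),
            "K_leak": np.array([s.K_leak for s in self.specs]),
            "m": np.empty(n),
            "cel": np.empty(n, dtype=np.bool_),
            "proto": np.empty(n, dtype=np.bool_),
            "alive": np.ones(n, dtype=np.bool_),
        }
        self._arrays = arr
        self.refresh_traits()
        return arr

    def refresh_traits(self) -> None:
        """Re-derive trait flags and maintenance burdens after mutation."""
        for i, (spec, traits) in enumerate(self):
            self._arrays["cel"][i] = traits.cellulolytic
            self._arrays["proto"][i] = traits.prototrophic
            self._arrays["m"][i] = maintenance_burden(
                traits, spec.strategy, self.params, self.burden_mode)

    def packed_arrays(self, burden_mode: BurdenMode = None) -> dict:
        if burden_mode is not None and BurdenMode(burden_mode) != self.burden_mode:
            self.burden_mode = BurdenMode(burden_mode)
            self.refresh_traits()
        return self._arrays

    def maintenance(self) -> np.ndarray:
        return self._arrays["m"].copy()

    def lose_function(self, species_index: int, function: str) -> None:
        traits = self.traits[species_index]
        if function == "cellulase":
            if not traits.cellulolytic:
                raise ParameterError("cellulase already lost")
            traits.cellulolytic = False
        elif function == "amino_acid_production":
            if not traits.prototrophic:
                raise ParameterError("amino-acid production already lost")
            traits.prototrophic = False
        else:
            raise ParameterError(f"unknown function {function!r}")
        self.refresh_traits()


def generate_community(seed, n: int = 20,
                       params: ParameterTable = DEFAULT_PARAMS,
                       initial_biomass: float = 1.0,
                       burden_mode: BurdenMode = BurdenMode.DEFAULT) -> Community:
    """Draw a random community of ``n`` species.

    Each species draws its functional group uniformly over the four
    groups and its life strategy uniformly over the two strategies
    (eight equiprobable profiles).  ``seed`` may be an int, a
    ``SeedSequence`` or a ``Generator``; identical seeds give identical
    rosters.
    """
    if n < 1:
        raise ParameterError("community size must be >= 1")
    rng = np.random.default_rng(seed)
    groups = list(FunctionalGroup)
    strategies = list(LifeStrategy)
    species = []
    for i in range(n):
        group = groups[rng.integers(4)]
        strategy = strategies[rng.integers(2)]
        species.append((params.species_spec(i, strategy), group.traits))
    return Community(species, params=params, initial_biomass=initial_biomass,
                     burden_mode=burden_mode)


def apply_mutations(community: Community, rate, rng,
                    generation: int = 0,
                    alive=None) -> list[MutationEvent]:
    """One generation of stochastic loss-of-function mutation.

    Each alive species independently suffers a mutation with
    probability ``rate``; a mutating species loses one still-possessed
    function, chosen uniformly if both remain.  Cheaters have nothing
    left to lose and generate no events.  Every mutation strictly
    decreases the species' maintenance burden.
    """
    if isinstance(rate, MutationRate):
        rate = rate.rate
    if not 0 <= rate <= 1:
        raise ParameterError("mutation rate must be a probability")
    events: list[MutationEvent] = []
    if rate == 0:
        return events
    n = community.size
    hits = rng.random(n) < rate
    for i in np.nonzero(hits)[0]:
        if alive is not None and not alive[i]:
            continue
        traits = community.traits[i]
        possessed = []
        if traits.cellulolytic:
            possessed.append("cellulase")
        if traits.prototrophic:
            possessed.append("amino_acid_production")
        if not possessed:
            continue
        lost = possessed[rng.integers(len(possessed))]
        community.lose_function(int(i), lost)
        events.append(MutationEvent(generation=generation,
                                    species_id=community.specs[i].id,
                                    lost_function=lost))
    return events
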