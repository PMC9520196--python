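import numpy as np
import pytest

from soilcom.community import Community, FunctionalGroup
from soilcom.model_core import DEFAULT_PARAMS, LifeStrategy


def build_community(profiles, params=DEFAULT_PARAMS, initial_biomass=1.0,
                    burden_mode="default"):
    """Community from explicit (strategy, group) profiles."""
    species = []
    for i, (strategy, group) in enumerate(profiles):
        strategy = LifeStrategy(strategy)
        group = FunctionalGroup(group)
        species.append((params.species_spec(i, strategy), group.traits))
    return Community(species, params=params, initial_biomass=initial_biomass,
                     burden_mode=burden_mode)


@pytest.fixture
def make_community():
    return build_community


@pytest.fixture
def params():
    return DEFAULT_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
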