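import numpy as np
import pytest

from microassembly import AssemblyModel, SpeciesTraits


@pytest.fixture
def neutral_symmetric():
    """Two species with identical traits, r = c = 1."""
    return (SpeciesTraits("A", 1.0, 1.0), SpeciesTraits("B", 1.0, 1.0))


@pytest.fixture
def asymmetric_dispersal():
    """Neutral division, A disperses twice as fast as B."""
    return (SpeciesTraits("A", 1.0, 2.0), SpeciesTraits("B", 1.0, 1.0))


@pytest.fixture
def neutral_model(neutral_symmetric):
    return AssemblyModel(species=neutral_symmetric, carrying_capacity=1000)


def make_traits(r_a, c_a, r_b, c_b):
    return (SpeciesTraits("A", r_a, c_a), SpeciesTraits("B", r_b, c_b))


def make_neutral_model(c_a, c_b, K, r=1.0):
    return AssemblyModel(
        species=(SpeciesTraits("A", r, c_a), SpeciesTraits("B", r, c_b)),
        carrying_capacity=K,
    )
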