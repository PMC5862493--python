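import numpy as np
import pytest

from photogain.cable import HHParams, PassiveParams, build_system
from photogain.morphology import (Arbor, MorphologySpec, Section,
                                  generate_arbor)


@pytest.fixture(scope="session")
def bipolar_arbor():
    """(2, 2, 6): the bipolar moderately branched reference arbor."""
    return generate_arbor(MorphologySpec(2, 2, 6))


@pytest.fixture(scope="session")
def chain_arbor():
    """(1, 1, 20): an unbranched 20-section cable for analytic checks."""
    return generate_arbor(MorphologySpec(1, 1, 20))


@pytest.fixture()
def soma_only_arbor():
    """An isolated soma (no dendrites)."""
    soma = Section(id=0, parent_id=-1, length=10.0, diameter=10.0,
                   depth_level=-1, pole_index=-1, path_distance_to_soma=0.0)
    return Arbor(soma=soma, sections=[])


@pytest.fixture()
def passive_bipolar_system(bipolar_arbor):
    return build_system(bipolar_arbor, passive=PassiveParams())


@pytest.fixture()
def hh_bipolar_system(bipolar_arbor):
    return build_system(bipolar_arbor, passive=PassiveParams(),
                        hh_soma=HHParams())
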