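import numpy as np
import pytest

from ffbalance.fixtures import (
    extended_coords,
    ideal_helix_coords,
    make_toy_topology,
    random_configuration,
)

MINIMAL_TOP = """\
[ defaults ]
1 2 yes 0.5 0.8333

[ atomtypes ]
CT 12.011 0.0 A 0.34 0.36
OW 15.999 0.0 A 0.3164 0.7749

[ moleculetype ]
LIG 3

[ atoms ]
1 CT 1 LIG C1 1 0.0 12.011

[ system ]
minimal

[ molecules ]
LIG 1
"""


@pytest.fixture(scope="session")
def toy_aqa():
    return make_toy_topology("AQA", n_water=2)


@pytest.fixture(scope="session")
def toy_adq():
    # ALA-ASP-GLN-ALA: keeps the GLN non-C-terminal so it carries a psi
    return make_toy_topology("ADQA", n_water=1)


@pytest.fixture(scope="session")
def toy_aaqaa3():
    return make_toy_topology("AAQAA" * 3, n_water=1)


@pytest.fixture(scope="session")
def helix15():
    return ideal_helix_coords(15)


@pytest.fixture(scope="session")
def extended15():
    return extended_coords(15)


@pytest.fixture()
def aqa_config(toy_aqa):
    return random_configuration(toy_aqa, seed=7)
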