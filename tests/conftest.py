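import numpy as np
import pytest

from nullelab.chem import ActionSpace, MoleculeState
from nullelab.synthetic import gen_molecule_library


@pytest.fixture(scope="session")
def small_library():
    """Thirty distinct random-walk molecules over C/N/O/F/S (seeded)."""
    return gen_molecule_library(11, 30, walk_length=5)


@pytest.fixture(scope="session")
def cno_space():
    return ActionSpace(allowed_elements=frozenset({"C", "N", "O"}), max_steps=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def methane():
    return MoleculeState("C")
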