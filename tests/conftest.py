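import numpy as np
import pytest

from reaxkit import fixtures


@pytest.fixture(scope="session")
def toy_ff():
    return fixtures.make_toy_forcefield()


@pytest.fixture(scope="session")
def ho_ff():
    return fixtures.make_toy_forcefield(elements=("H", "O"))


@pytest.fixture()
def water():
    return fixtures.water()


@pytest.fixture()
def water_dimer():
    return fixtures.water_dimer()


@pytest.fixture()
def fe2s2():
    return fixtures.fe2s2()


@pytest.fixture()
def fe2s2_w4():
    return fixtures.fe2s2_w4()


def jiggled(s, sd=0.05, seed=0):
    """Randomly displaced copy of a structure (breaks symmetry)."""
    rng = np.random.default_rng(seed)
    return s.with_coords(s.coords + sd * rng.normal(size=s.coords.shape))
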