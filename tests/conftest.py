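import numpy as np
import pytest

from egmslab import (
    DEFAULT_CONDUCTIVITIES,
    DEFAULT_MEMBRANE,
    ConductivitySet,
    SlabModel,
)


@pytest.fixture(scope="session")
def cs():
    """Reference bidomain conductivity set (S/m)."""
    return DEFAULT_CONDUCTIVITIES


@pytest.fixture(scope="session")
def slab0(cs):
    """5 mm wall, wave propagating along the fibers."""
    return SlabModel(cs, L=5.0, psi=0.0)


@pytest.fixture(scope="session")
def slab90(cs):
    """5 mm wall, wave propagating across the fibers."""
    return SlabModel(cs, L=5.0, psi=90.0)


@pytest.fixture(scope="session")
def mem():
    return DEFAULT_MEMBRANE


@pytest.fixture(scope="session")
def uniform_cs():
    """Isotropic myocardium whose total conductivity matches the bath:
    the three-layer problem degenerates to a homogeneous medium."""
    return ConductivitySet(
        g_i_l=0.2, g_i_t=0.2, g_e_l=0.5, g_e_t=0.5, g_B=0.7, g_T=0.7
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230710)
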