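import numpy as np
import pytest
from hypothesis import settings

import nicheweb as nw

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_community(rng):
    """A 6+6 random community at high connectance, sigma = 0.1."""
    return nw.BipartiteCommunity.random(6, 6, 0.4, 0.1, rng)


@pytest.fixture
def params():
    return nw.DynamicsParams()


def make_pair_community(gamma_strength=0.1, omega_c=0.0, center_gap=0.0):
    """1+1 linked pair with controllable coupling, for hand-checked cases."""
    comm = nw.BipartiteCommunity(
        centers_A=[0.5], centers_P=[0.5 + center_gap], width=0.1,
        theta=np.ones((1, 1)),
    )
    intens = nw.InteractionIntensities(gamma_strength, omega_c)
    return comm, nw.build_couplings(comm, intens)
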