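import numpy as np
import pytest

from nanotherm import make_grid, spherical_tumour_state
from nanotherm.transport import TransportParams


@pytest.fixture(scope="session")
def quarter_grid():
    return make_grid(60, 60, 0.5, 0.5)


@pytest.fixture(scope="session")
def quarter_state(quarter_grid):
    return spherical_tumour_state(quarter_grid, 0.4, (0.0, 0.5))


@pytest.fixture(scope="session")
def tparams():
    return TransportParams()


def uniform_state(grid, pl=0.0, eps_v=0.028, pt=None, pv=None,
                  St=0.0, Sh=0.6, Sl=0.4, eps=0.8):
    """Spatially uniform tissue state (no gradients: pure 0D dynamics)."""
    from nanotherm.microenv import TissueState

    n = grid.n_nodes
    return TissueState(
        grid=grid, eps=np.full(n, eps), eps_v=np.full(n, eps_v),
        St=np.full(n, St), Sh=np.full(n, Sh), Sl=np.full(n, Sl),
        pl=np.full(n, pl),
        pt=np.full(n, pl if pt is None else pt),
        pv=np.full(n, pl + 400.0 if pv is None else pv),
    )
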