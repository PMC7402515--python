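import numpy as np
import pytest

from aisdyn.cable import ChannelDensities, build_bas


@pytest.fixture(scope="session")
def passive_leaky_model():
    """Passive cable with an electrically relevant axonal leak, for
    comparison against the exact ladder-network solution."""
    dens = ChannelDensities(g_leak=10.0)  # pS/um^2: makes the axon lossy
    return build_bas(densities=dens, d=25.0).passive_copy()


@pytest.fixture(scope="session")
def default_model():
    return build_bas(d=25.0)


def ladder_steady_state(model, i_soma_nA: float) -> np.ndarray:
    """Exact steady state of the passive compartment ladder: solve G V = b."""
    n = model.n_compartments
    G = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(n):
        G[i, i] += model.g_leak[i]
        b[i] += model.g_leak[i] * model.densities.E_leak
    for i in range(n - 1):
        g = model.g_axial[i]
        G[i, i] += g
        G[i + 1, i + 1] += g
        G[i, i + 1] -= g
        G[i + 1, i] -= g
    b[0] += i_soma_nA * 1e3  # pA
    return np.linalg.solve(G, b)
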