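import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cartrend as ct

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def connected_sublattices_3x3():
    """All lattices on connected occupied subsets of a 3x3 rook grid."""
    import networkx as nx

    cells = [(i, j) for i in range(3) for j in range(3)]
    out = []
    for mask in range(1, 1 << 9):
        sub = [cells[k] for k in range(9) if mask >> k & 1]
        if len(sub) < 2:
            continue
        g = nx.Graph()
        g.add_nodes_from(sub)
        g.add_edges_from(
            (a, b)
            for a in sub
            for b in sub
            if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1
        )
        if g.number_of_edges() and nx.is_connected(g):
            out.append(sub)
    return out


@pytest.fixture(scope="session")
def grid_2x2():
    return ct.build_lattice([(0, 0), (1, 0), (0, 1), (1, 1)], connectivity="strict")


@pytest.fixture(scope="session")
def grid_3x3():
    return ct.build_lattice(
        [(i, j) for i in range(3) for j in range(3)], connectivity="strict"
    )


@pytest.fixture(scope="session")
def small_fit():
    """A real (tiny) simulated survey and its fitted model, shared read-only."""
    data, truth = ct.simulate(shape=(4, 4), n_years=6, seed=3)
    model = ct.CARTrendModel(n_chains=2, n_keep=800, n_burn=400, random_state=3)
    model.fit(data)
    return data, truth, model


def make_draws(alpha, b, sig2, lattice, years):
    """Hand-built PosteriorDraws (1 chain) for deterministic trend algebra.

    alpha: (n, T); b: (n, C, T) centered per year; sig2: (n,).
    """
    n, T = alpha.shape
    return ct.PosteriorDraws(
        alpha=alpha[None],
        omega=np.zeros((1, n, 1)),
        b=b[None],
        sig2=np.asarray(sig2)[None],
        tau2=np.ones((1, n)),
        years=np.asarray(years),
        cell_ids=[c.id for c in lattice.cells],
        obs_labels=np.array(["o0"]),
        lattice=lattice,
        config=ct.ModelConfig(n_chains=1, n_keep=n, n_burn=0),
    )
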