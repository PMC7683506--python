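import numpy as np
import pytest

from crnflow.network import (example_two_pair_network, parse_reaction_text,
                             random_db_network, solve_detailed_balance)


@pytest.fixture(scope="session")
def linear_db():
    """Linear birth-death network 0 <-> X with unit rates (c* = 1)."""
    net = parse_reaction_text("species: X\n0 <-> X ; kf=1 kb=1\n")
    return net, solve_detailed_balance(net)


@pytest.fixture(scope="session")
def two_pair_db():
    """Two-reaction-pair scalar network at its detailed-balance point a=2, b=1."""
    net = example_two_pair_network(2, 1)
    return net, solve_detailed_balance(net)


@pytest.fixture(scope="session")
def coupled_db():
    """The two-species network X1 <-> 2 X2 (conservation 2 c1 + c2)."""
    net = parse_reaction_text("species: X1 X2\nX1 <-> 2 X2 ; kf=1 kb=1\n")
    return net, solve_detailed_balance(net)


@pytest.fixture(scope="session")
def random_nets():
    """A batch of seeded random detailed-balance networks with test points c > 0."""
    out = []
    rng = np.random.default_rng(12345)
    for k in range(20):
        net, db = random_db_network(rng.integers(1, 4), rng.integers(1, 5),
                                    max_order=2, seed=1000 + k)
        c = db.c_star * rng.uniform(0.4, 2.0, size=net.n_species)
        out.append((net, db, c))
    return out
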