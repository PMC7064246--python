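import numpy as np
import pytest

from radeflow.core import Link, Network, Node, NodeRole, TopologySpec, TopologyShape


@pytest.fixture
def single_link_network():
    """One resource (V=100) feeding one consumer over unit resistance.

    The analytic circuit: P(I) = I(100 - I), peak at I = 50 with V_C = 50,
    first negative power beyond I = 100.
    """
    nodes = [
        Node(0, NodeRole.RESOURCE, [0.0, 0.0], potential=100.0),
        Node(1, NodeRole.CONSUMER, [1.0, 0.0]),
    ]
    return Network(nodes, [Link(0, 1, 1.0)])


@pytest.fixture
def chain_network():
    """resource(100) — c1 — c2 with unit resistances.

    Hand nodal analysis at I_C = 10 per consumer: the first link carries 20
    units (drop 20), the second 10 (drop 10), so V_c1 = 80, V_c2 = 70 and
    the effective resistances are {2, 3}.
    """
    nodes = [
        Node(0, NodeRole.RESOURCE, [0.0, 0.0], potential=100.0),
        Node(1, NodeRole.CONSUMER, [1.0, 0.0]),
        Node(2, NodeRole.CONSUMER, [2.0, 0.0]),
    ]
    return Network(nodes, [Link(0, 1, 1.0), Link(1, 2, 1.0)])


@pytest.fixture
def radial8():
    from radeflow.generators import radial_burst

    return radial_burst(8, radius=1.0, resource_potential=100.0)


def make_random_network(rng: np.random.Generator, max_nodes: int = 30) -> Network:
    """Small random connected network for solver equivalence sweeps.

    Built directly (not via the spatial generator) so the solver tests
    exercise arbitrary admissible structures: random node roles, random
    positive resistances, connectivity enforced by a random spanning tree.
    """
    n = int(rng.integers(3, max_nodes + 1))
    n_res = int(rng.integers(1, max(2, n // 5) + 1))
    roles = [NodeRole.RESOURCE] * n_res
    for _ in range(n - n_res):
        roles.append(
            NodeRole.CONSUMER if rng.uniform() < 0.8 else NodeRole.BRANCH_POINT
        )
    if not any(r is NodeRole.CONSUMER for r in roles):
        roles[-1] = NodeRole.CONSUMER
    v_r = float(rng.uniform(50, 5000))
    nodes = [
        Node(
            i,
            roles[i],
            rng.uniform(0, 100, 2),
            potential=v_r if roles[i] is NodeRole.RESOURCE else None,
        )
        for i in range(n)
    ]
    links = {}
    first_consumer = next(i for i in range(n) if roles[i] is NodeRole.CONSUMER)
    order = [first_consumer] + [i for i in rng.permutation(n) if i != first_consumer]
    for k in range(1, n):  # random spanning tree rooted at a consumer: connects everything
        a = int(order[k])
        b = int(order[int(rng.integers(0, k))])
        if roles[a] is NodeRole.RESOURCE and roles[b] is NodeRole.RESOURCE:
            b = first_consumer  # always an admissible attachment point
        links[frozenset((a, b))] = Link(a, b, float(rng.uniform(0.5, 10)), float(rng.uniform(0.5, 4)))
    extra = int(rng.integers(0, 2 * n))
    for _ in range(extra):
        a, b = rng.integers(0, n, 2)
        a, b = int(a), int(b)
        if a == b or frozenset((a, b)) in links:
            continue
        if roles[a] is NodeRole.RESOURCE and roles[b] is NodeRole.RESOURCE:
            continue
        links[frozenset((a, b))] = Link(a, b, float(rng.uniform(0.5, 10)), float(rng.uniform(0.5, 4)))
    net = Network(nodes, list(links.values()))
    from radeflow.core import validate

    if not validate(net).ok:  # spanning-tree skip above can rarely disconnect
        return make_random_network(rng, max_nodes)
    return net
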