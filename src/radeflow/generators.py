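"""Network generators: random spatial, radial burst, and branching families.

These produce every network family the simulator studies and double as the
test-fixture factory.  All generators are deterministic under a fixed seed.

Resource potentials are a free boundary condition of the model (raising or
lowering them rescales every consumer potential linearly), so by default
each generator calibrates them such that the total-power peak falls at a
target per-consumer demand of 100 flow units — comfortably inside the
default 1…1000 sweep grid.  Pass an explicit ``resource_potential`` to
override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .core import (
    InvalidParameterError,
    Link,
    Network,
    Node,
    NodeRole,
    TopologyShape,
    TopologySpec,
    validate,
)

__all__ = [
    "GeneratorParams",
    "GenerationError",
    "UnsupportedStructureError",
    "topology_size",
    "sample_point",
    "random_network",
    "radial_burst",
    "fully_branched",
    "evolved_branching_base",
    "evolved_branching",
    "apply_strength_rule",
    "calibrate_resource_potential",
]

#: Demand level (flow units per consumer) the auto-calibrated resource
#: potential places the total-power peak at.
DEFAULT_TARGET_PEAK_DEMAND = 100.0


class GenerationError(RuntimeError):
    """Generator could not produce a valid (connected) network."""


class UnsupportedStructureError(ValueError):
    """Operation applied to a network family it is not defined for."""


def topology_size(n_consumers: int, n_resources: int) -> float:
    """Auto-sized topology extent: 10·nC · 100·nR generalised length units.

    Scales the plane side (or sphere radius) with the node counts so that
    multi-node networks keep meaningfully large inter-node distances.
    """
    if n_consumers < 1 or n_resources < 1:
        raise InvalidParameterError(
            f"need at least one consumer and one resource, got "
            f"nC={n_consumers}, nR={n_resources}"
        )
    return 10.0 * n_consumers * 100.0 * n_resources


def sample_point(topology: TopologySpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one uniform point in (or on) the topology.

    PLANE: each coordinate uniform on [0, size].  SPHERE: uniform within
    the ball of radius ``size``.  SPHERE_SURFACE: uniform on the sphere of
    radius ``size``.
    """
    if topology.shape is TopologyShape.PLANE:
        return rng.uniform(0.0, topology.size, size=2)
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    while norm < 1e-12:  # pragma: no cover - probability ~0
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
    direction /= norm
    if topology.shape is TopologyShape.SPHERE_SURFACE:
        return topology.size * direction
    if topology.shape is TopologyShape.SPHERE:
        radius = topology.size * rng.uniform() ** (1.0 / 3.0)
        return radius * direction
    raise InvalidParameterError(f"unknown topology shape {topology.shape!r}")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters for the random spatial network generator.

    ``p_no_connection`` is the probability that an admissible node pair is
    *not* linked; admissible pairs are all pairs except resource–resource.
    With ``topology=None`` the extent is auto-sized from the node counts.
    """

    n_consumers: int = 20
    n_resources: int = 1
    n_branch_points: int = 0
    p_no_connection: float = 0.8
    shape: TopologyShape = TopologyShape.PLANE
    topology: TopologySpec | None = None
    use_strength: bool = False
    strength_exponent: float = 2.0
    resource_potential: float | None = None
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_no_connection <= 1.0):
            raise InvalidParameterError(
                f"p_no_connection must lie in [0,1], got {self.p_no_connection}"
            )
        if min(self.n_consumers, self.n_resources) < 1 or self.n_branch_points < 0:
            raise InvalidParameterError("node counts out of range")

    def resolved_topology(self) -> TopologySpec:
        if self.topology is not None:
            return self.topology
        return TopologySpec(self.shape, topology_size(self.n_consumers, self.n_resources))


def calibrate_resource_potential(
    network: Network, target_peak_demand: float = DEFAULT_TARGET_PEAK_DEMAND
) -> Network:
    """Set all resource potentials so the power peak sits at a target demand.

    The maximum of total power over demand occurs at I* = V_R / (2·R̄_E)
    with R̄_E the mean consumer effective resistance, which is independent
    of V_R; one probe solve therefore fixes V_R = 2·I*·R̄_E.  Potentials
    are set equal across resources (the model's mean-field identities are
    exact for equal resource potentials) and the network is returned.
    """
    from .solver import direct_solve  # local import to avoid a cycle

    for node in network.resources:
        node.potential = 1.0
    record = direct_solve(network, 1.0)
    effective = 1.0 - record.consumer_potentials  # R_E at V_R=1, I=1
    mean_re = float(effective.mean())
    if mean_re <= 0:
        raise GenerationError("non-positive mean effective resistance; cannot calibrate")
    v_r = 2.0 * target_peak_demand * mean_re
    for node in network.resources:
        node.potential = v_r
    return network


def _finalise_potentials(network: Network, resource_potential: float | None) -> Network:
    if resource_potential is not None:
        for node in network.resources:
            node.potential = resource_potential
        return network
    return calibrate_resource_potential(network)


def random_network(params: GeneratorParams) -> Network:
    """Random spatial network: uniform node placement, Bernoulli links.

    Every node pair except resource–resource receives a link with
    probability 1 − p_no_connection; link lengths are Euclidean distances
    and strengths are 1 unless the strength rule is requested.  Generation
    retries (with fresh draws) until every consumer and branch point is
    reachable from a resource, up to ``params.max_retries``.
    """
    rng = np.random.default_rng(params.seed)
    topo = params.resolved_topology()
    for _ in range(params.max_retries):
        nodes: list[Node] = []
        nid = 0
        for _ in range(params.n_resources):
            nodes.append(Node(nid, NodeRole.RESOURCE, sample_point(topo, rng), potential=1.0))
            nid += 1
        for _ in range(params.n_consumers):
            nodes.append(Node(nid, NodeRole.CONSUMER, sample_point(topo, rng)))
            nid += 1
        for _ in range(params.n_branch_points):
            nodes.append(Node(nid, NodeRole.BRANCH_POINT, sample_point(topo, rng)))
            nid += 1

        links: list[Link] = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = nodes[i], nodes[j]
                if a.role is NodeRole.RESOURCE and b.role is NodeRole.RESOURCE:
                    continue
                if rng.uniform() >= 1.0 - params.p_no_connection:
                    continue
                length = float(np.linalg.norm(a.coords - b.coords))
                if length <= 0:  # coincident points; skip the degenerate link
                    continue
                links.append(Link(a.id, b.id, length))

        network = Network(nodes, links, topo)
        report = validate(network)
        reachable = report.ok and _all_reachable(network)
        if reachable:
            return _finalise_potentials(network, params.resource_potential)
    raise GenerationError(
        f"could not generate a connected network in {params.max_retries} attempts "
        f"(p_no_connection={params.p_no_connection})"
    )


def _all_reachable(network: Network) -> bool:
    g = network.graph()
    reachable: set[int] = set()
    for r in network.resources:
        reachable |= nx.node_connected_component(g, r.id)
    return all(n.id in reachable for n in network.nodes)


def radial_burst(
    n_consumers: int,
    radius: float = 100.0,
    resource_potential: float | None = None,
) -> Network:
    """Idealised radial burst: one central resource, spoke links of equal length.

    Every consumer is connected directly and only to the resource by a link
    of length ``radius`` and strength 1, so all link (and effective)
    resistances are identical and the consumer potential spread is zero at
    every flow level.
    """
    if n_consumers < 1:
        raise InvalidParameterError("need at least one consumer")
    topo = TopologySpec(TopologyShape.PLANE, 2.0 * radius)
    centre = np.array([radius, radius])
    nodes = [Node(0, NodeRole.RESOURCE, centre, potential=1.0)]
    links = []
    for k in range(n_consumers):
        angle = 2.0 * math.pi * k / n_consumers
        coords = centre + radius * np.array([math.cos(angle), math.sin(angle)])
        nodes.append(Node(k + 1, NodeRole.CONSUMER, coords, level=0))
        links.append(Link(0, k + 1, radius))
    return _finalise_potentials(Network(nodes, links, topo), resource_potential)


def fully_branched(
    levels: int = 8,
    branching_factor: int = 2,
    level_lengths: np.ndarray | list[float] | None = None,
    base_length: float = 100.0,
    resource_potential: float | None = None,
) -> Network:
    """Self-similar branched network with a consumer at every junction.

    One root resource; every tree node below it is a consumer.  Level l
    (l = 0 nearest the resource) holds branching_factor**(l+1) consumers.
    Link lengths are *set* per level rather than Euclidean — the default is
    self-similar halving, level l links of length base_length / 2**(l+1).
    """
    if levels < 1 or branching_factor < 2:
        raise InvalidParameterError("need levels >= 1 and branching_factor >= 2")
    if level_lengths is None:
        level_lengths = [base_length / 2.0 ** (l + 1) for l in range(levels)]
    level_lengths = np.asarray(level_lengths, dtype=float)
    if level_lengths.shape != (levels,) or np.any(level_lengths <= 0):
        raise InvalidParameterError("level_lengths must hold one positive length per level")

    nodes = [Node(0, NodeRole.RESOURCE, np.array([0.0, 0.0]), potential=1.0)]
    links: list[Link] = []
    radii = np.cumsum(level_lengths)
    parents = [0]
    nid = 1
    for level in range(levels):
        children: list[int] = []
        count = branching_factor ** (level + 1)
        for k in range(count):
            angle = 2.0 * math.pi * (k + 0.5) / count
            coords = radii[level] * np.array([math.cos(angle), math.sin(angle)])
            nodes.append(Node(nid, NodeRole.CONSUMER, coords, level=level))
            parent = parents[k // branching_factor]
            links.append(Link(parent, nid, float(level_lengths[level])))
            children.append(nid)
            nid += 1
        parents = children
    topo = TopologySpec(TopologyShape.PLANE, 2.0 * float(radii[-1]))
    return _finalise_potentials(Network(nodes, links, topo), resource_potential)


def evolved_branching_base(
    n_consumers: int = 512,
    radius: float = 100.0,
    jitter: float = 0.05,
    seed: int = 0,
    resource_potential: float | None = None,
) -> Network:
    """Nearly radial burst used as the starting point of branching evolution.

    Consumers sit on a circle around the central resource at slightly
    jittered radii radius·(1 + u), u ~ U(0, jitter), each linked directly
    to the resource by a link of its own radial length — so the starting
    network carries a small amount of structural inequality.
    """
    if n_consumers < 1:
        raise InvalidParameterError("need at least one consumer")
    rng = np.random.default_rng(seed)
    topo = TopologySpec(TopologyShape.PLANE, 4.0 * radius)
    centre = np.zeros(2)
    nodes = [Node(0, NodeRole.RESOURCE, centre, potential=1.0)]
    links = []
    for k in range(n_consumers):
        angle = 2.0 * math.pi * (k + 0.5) / n_consumers
        r_k = radius * (1.0 + rng.uniform(0.0, jitter))
        coords = r_k * np.array([math.cos(angle), math.sin(angle)])
        nodes.append(Node(k + 1, NodeRole.CONSUMER, coords, level=0))
        links.append(Link(0, k + 1, r_k))
    return _finalise_potentials(Network(nodes, links, topo), resource_potential)


def evolved_branching(
    base: Network,
    stage: int,
    branching_factor: int = 2,
    max_stage: int = 7,
) -> Network:
    """Insert ``stage`` levels of zero-demand branch points into a radial base.

    Consumers (count and positions) are unchanged across stages.  At stage
    k the consumers are partitioned, in angular order, into groups served
    by a binary-tree trunk of branch points: the level-j branch points
    (j = 1…k) sit at path radius D·(1 − 2⁻ʲ) from the resource and carry
    set link lengths D/2ʲ, where D is the base's nominal spoke radius.
    Deepest-level branch points connect to their consumers by the radial
    remainder r_i − D·(1 − 2⁻ᵏ); at the final stage this hop is replaced
    by the set self-similar length D/2^max_stage, so every consumer sits at
    the same path distance D from the resource (despite slightly different
    Euclidean radii) and the trajectory's inequality vanishes.  Average
    link length shortens, and total link length strictly decreases, with
    every added stage.
    """
    if not (0 <= stage <= max_stage):
        raise InvalidParameterError(f"stage must lie in [0, {max_stage}], got {stage}")
    resources = base.resources
    if len(resources) != 1:
        raise UnsupportedStructureError("evolved branching needs a single-resource base")
    centre0 = base.resources[0].coords
    consumers = sorted(
        base.consumers,
        key=lambda n: math.atan2(n.coords[1] - centre0[1], n.coords[0] - centre0[0]),
    )
    n_c = len(consumers)
    if n_c % branching_factor**max_stage != 0:
        raise InvalidParameterError(
            f"{n_c} consumers cannot be partitioned into {branching_factor}^{max_stage} groups"
        )
    root = resources[0]
    centre = root.coords
    radii = np.array([float(np.linalg.norm(c.coords - centre)) for c in consumers])
    d_nominal = float(radii.min())  # base spokes are D·(1+u), u >= 0

    nodes = [Node(root.id, NodeRole.RESOURCE, centre.copy(), potential=root.potential)]
    nodes += [
        Node(c.id, NodeRole.CONSUMER, c.coords.copy(), level=c.level) for c in consumers
    ]
    links: list[Link] = []
    if stage == 0:
        for c, r in zip(consumers, radii):
            links.append(Link(root.id, c.id, float(r)))
        return Network(nodes, links, base.topology)

    nid = max(n.id for n in base.nodes) + 1
    # level-j branch point count: (nC / f^max_stage) · f^(j-1)
    parents = [root.id]
    parent_groups = [list(range(n_c))]
    for j in range(1, stage + 1):
        count = (n_c // branching_factor**max_stage) * branching_factor ** (j - 1)
        path_radius = d_nominal * (1.0 - 2.0 ** (-j))
        length_j = d_nominal / 2.0**j
        group_size = n_c // count
        new_parents: list[int] = []
        new_groups: list[list[int]] = []
        for g in range(count):
            members = list(range(g * group_size, (g + 1) * group_size))
            angles = [
                math.atan2(consumers[m].coords[1] - centre[1], consumers[m].coords[0] - centre[0])
                for m in members
            ]
            mean_angle = _circular_mean(angles)
            coords = centre + path_radius * np.array([math.cos(mean_angle), math.sin(mean_angle)])
            nodes.append(Node(nid, NodeRole.BRANCH_POINT, coords, level=j))
            # parent: the existing trunk node whose group contains this one
            parent = _containing_parent(parents, parent_groups, members[0])
            links.append(Link(parent, nid, length_j))
            new_parents.append(nid)
            new_groups.append(members)
            nid += 1
        parents, parent_groups = new_parents, new_groups

    hop_radius = d_nominal * (1.0 - 2.0 ** (-stage))
    set_hop = d_nominal / 2.0**max_stage
    for g, members in enumerate(parent_groups):
        for m in members:
            if stage == max_stage:
                length = set_hop
            else:
                length = float(radii[m] - hop_radius)
            links.append(Link(parents[g], consumers[m].id, length))
    return Network(nodes, links, base.topology)


def _circular_mean(angles: list[float]) -> float:
    return math.atan2(
        sum(math.sin(a) for a in angles) / len(angles),
        sum(math.cos(a) for a in angles) / len(angles),
    )


def _containing_parent(parents: list[int], groups: list[list[int]], member: int) -> int:
    for pid, grp in zip(parents, groups):
        if member in grp:
            return pid
    raise RuntimeError("trunk bookkeeping broke: consumer not in any group")


def apply_strength_rule(network: Network, exponent: float = 2.0) -> Network:
    """Set tree-link strengths to (downstream consumer count) ** exponent.

    With uniform per-consumer demand the flow on a tree link is exactly
    I_C times its downstream consumer count, so this realises S ∝ I^exponent
    statically from the topology; with exponent 2 the transport loss on a
    link becomes I_C²·L, a function of link length alone.  Strengths are
    then fixed for the whole sweep.  Mutates and returns the network.
    """
    if len(network.resources) != 1 or not network.is_tree():
        raise UnsupportedStructureError(
            "the strength rule is defined for single-resource tree networks"
        )
    g = network.graph()
    root = network.resources[0].id
    order = list(nx.dfs_postorder_nodes(g, source=root))
    parent = {v: u for u, v in nx.bfs_edges(g, source=root)}
    counts: dict[int, int] = {}
    for v in order:
        c = 1 if network.node(v).role is NodeRole.CONSUMER else 0
        c += sum(counts[w] for w in g.neighbors(v) if parent.get(w) == v)
        counts[v] = c
    for link in network.links:
        child = link.node_b if parent.get(link.node_b) == link.node_a else link.node_a
        link.strength = float(counts[child]) ** exponent
    return network
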