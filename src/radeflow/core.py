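"""Network data model and flow-law primitives.

The model is an electrical analogue of resource transport: a network of
*resource* nodes held at fixed potential, *consumer* nodes that each draw a
specified resource flow, and optional zero-demand *branch points*, joined by
links whose resistance is the ratio of link length to link strength.  All
quantities are in generalised (dimensionless) units of potential, flow,
resistance and power — the analogue applies equally to Ohm's, Darcy's,
Fick's or Fourier's law, so no physical unit system is imposed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NodeRole",
    "TopologyShape",
    "Node",
    "Link",
    "TopologySpec",
    "DemandSpec",
    "Network",
    "ValidationFinding",
    "ValidationReport",
    "InvalidLinkError",
    "InvalidParameterError",
    "NetworkValidationError",
    "link_resistance",
    "link_flow",
    "consumer_power",
    "link_loss",
    "validate",
]


class InvalidLinkError(ValueError):
    """A link with non-positive length, strength or resistance."""


class InvalidParameterError(ValueError):
    """A structurally invalid parameter value."""


class NetworkValidationError(ValueError):
    """Raised when an operation requires a clean validation report."""


class NodeRole(enum.Enum):
    RESOURCE = "resource"
    CONSUMER = "consumer"
    BRANCH_POINT = "branch_point"


class TopologyShape(enum.Enum):
    PLANE = "PLANE"
    SPHERE = "SPHERE"
    SPHERE_SURFACE = "SPHERE_SURFACE"


@dataclass
class Node:
    """A located network node.

    Resource potentials are boundary conditions: strictly positive and held
    constant for the whole simulation.  Consumer and branch-point potentials
    are solved; they start as ``None`` and may legitimately go negative late
    in a demand sweep.  ``level`` is a depth label used by the branched
    network families (0 = closest consumer level to the resource).
    """

    id: int
    role: NodeRole
    coords: np.ndarray
    potential: float | None = None
    level: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.role is NodeRole.RESOURCE:
            if self.potential is None or self.potential <= 0:
                raise InvalidParameterError(
                    f"resource node {self.id} needs a strictly positive potential, "
                    f"got {self.potential!r}"
                )


@dataclass
class Link:
    """An undirected connection between two nodes.

    Resistance is always the derived quantity L/S; it is exposed as a
    property so that any mutation of length or strength is reflected
    immediately and the identity can never go stale.
    """

    node_a: int
    node_b: int
    length: float
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise InvalidLinkError(f"self-link at node {self.node_a}")
        if self.length <= 0 or self.strength <= 0:
            raise InvalidLinkError(
                f"link ({self.node_a},{self.node_b}): length and strength must be "
                f"positive, got L={self.length}, S={self.strength}"
            )

    @property
    def resistance(self) -> float:
        return self.length / self.strength

    @property
    def endpoints(self) -> frozenset[int]:
        return frozenset((self.node_a, self.node_b))


@dataclass(frozen=True)
class TopologySpec:
    """Shape and size of the space the nodes occupy.

    ``size`` is the plane side length or the sphere radius, in generalised
    length units.
    """

    shape: TopologyShape = TopologyShape.PLANE
    size: float = 100.0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise InvalidParameterError(f"topology size must be positive, got {self.size}")

    @property
    def ndim(self) -> int:
        return 2 if self.shape is TopologyShape.PLANE else 3


@dataclass(frozen=True)
class DemandSpec:
    """Uniform per-consumer demand schedule for the sweep.

    Default schedule: start at 1 flow unit per consumer, step by 0.1, stop
    at 1000 (or earlier, when total network power turns negative).
    """

    start: float = 1.0
    step: float = 0.1
    stop: float = 1000.0

    def __post_init__(self) -> None:
        if self.start <= 0 or self.step <= 0 or self.stop < self.start:
            raise InvalidParameterError(f"bad demand schedule {self}")

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)


def link_resistance(link: Link) -> float:
    """Resistance of a link: length over strength."""
    return link.resistance


def link_flow(delta_v: float, resistance: float) -> float:
    """Flow driven across a resistance by a potential gradient (linear flow law).

    Positive flow runs from the higher- to the lower-potential endpoint.
    """
    if resistance <= 0:
        raise InvalidLinkError(f"resistance must be positive, got {resistance}")
    return delta_v / resistance


def consumer_power(v_c: float, i_c: float) -> float:
    """Final power delivered to a consumer: demand times consumer potential.

    Negative values are meaningful — they terminate the demand sweep.
    """
    return i_c * v_c


def link_loss(flow: float, resistance: float) -> float:
    """Power dissipated in transport across a link: I²R."""
    if resistance <= 0:
        raise InvalidLinkError(f"resistance must be positive, got {resistance}")
    return flow * flow * resistance


@dataclass(frozen=True)
class ValidationFinding:
    kind: str
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, kind: str, message: str) -> None:
        self.findings.append(ValidationFinding(kind, message))

    def kinds(self) -> set[str]:
        return {f.kind for f in self.findings}


class Network:
    """Node set plus symmetric link structure and topology metadata.

    Links are stored once per unordered pair; the connection structure is
    symmetric by construction.  Absent links are represented by explicit
    absence — a ``noConnection`` sentinel only exists at the CSV boundary.
    """

    def __init__(
        self,
        nodes: Sequence[Node],
        links: Iterable[Link],
        topology: TopologySpec | None = None,
    ) -> None:
        self.nodes: list[Node] = list(nodes)
        self.topology = topology or TopologySpec()
        self._by_id: dict[int, Node] = {n.id: n for n in self.nodes}
        if len(self._by_id) != len(self.nodes):
            raise InvalidParameterError("duplicate node ids")
        self.links: list[Link] = []
        seen: set[frozenset[int]] = set()
        for link in links:
            if link.endpoints in seen:
                raise InvalidLinkError(f"duplicate link {set(link.endpoints)}")
            if link.node_a not in self._by_id or link.node_b not in self._by_id:
                raise InvalidLinkError(f"link {set(link.endpoints)} references unknown node")
            seen.add(link.endpoints)
            self.links.append(link)

    # -- node accessors -------------------------------------------------

    def node(self, node_id: int) -> Node:
        return self._by_id[node_id]

    def nodes_with_role(self, role: NodeRole) -> list[Node]:
        return [n for n in self.nodes if n.role is role]

    @property
    def resources(self) -> list[Node]:
        return self.nodes_with_role(NodeRole.RESOURCE)

    @property
    def consumers(self) -> list[Node]:
        return self.nodes_with_role(NodeRole.CONSUMER)

    @property
    def branch_points(self) -> list[Node]:
        return self.nodes_with_role(NodeRole.BRANCH_POINT)

    @property
    def n_consumers(self) -> int:
        return len(self.consumers)

    # -- derived structure ---------------------------------------------

    def total_link_length(self) -> float:
        return float(sum(l.length for l in self.links))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, role=n.role)
        for l in self.links:
            g.add_edge(l.node_a, l.node_b, length=l.length, resistance=l.resistance)
        return g

    def connection_matrix(self, no_connection: float = -1.0) -> np.ndarray:
        """Dense symmetric strength matrix with a sentinel for absent links.

        Row/column order follows ``self.nodes``; purely an interchange
        format — the sentinel never enters any computation.
        """
        n = len(self.nodes)
        index = {node.id: i for i, node in enumerate(self.nodes)}
        m = np.full((n, n), no_connection, dtype=float)
        for l in self.links:
            i, j = index[l.node_a], index[l.node_b]
            m[i, j] = m[j, i] = l.strength
        return m

    def is_tree(self) -> bool:
        g = self.graph()
        return nx.is_connected(g) and g.number_of_edges() == g.number_of_nodes() - 1


def validate(network: Network, connection_matrix: np.ndarray | None = None) -> ValidationReport:
    """Structural health check; a clean report is a precondition of solving.

    Reports (rather than raises) unreachable consumers, degenerate links,
    missing resources and coordinate-dimension mismatches.  When a raw
    connection matrix is supplied (e.g. as read from CSV before network
    construction), asymmetric entries are reported too; the in-memory link
    store is symmetric by construction.
    """
    report = ValidationReport()
    if connection_matrix is not None:
        m = np.asarray(connection_matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            report.add("asymmetry", f"connection matrix is not square: shape {m.shape}")
        else:
            bad = np.argwhere(m != m.T)
            for i, j in bad[bad[:, 0] < bad[:, 1]]:
                report.add("asymmetry", f"connection matrix entries ({i},{j}) and ({j},{i}) differ")
    if not network.resources:
        report.add("no_resource", "network has no resource node")
    ndim = network.topology.ndim
    for node in network.nodes:
        if node.coords.shape != (ndim,):
            report.add(
                "dimension_mismatch",
                f"node {node.id} has {node.coords.shape[0]}-d coords in a {ndim}-d topology",
            )
    for link in network.links:
        if link.length <= 0 or link.strength <= 0:
            report.add("degenerate_link", f"link {set(link.endpoints)} has L={link.length}, S={link.strength}")
    if network.resources:
        g = network.graph()
        reachable: set[int] = set()
        for r in network.resources:
            reachable |= nx.node_connected_component(g, r.id)
        for c in network.consumers:
            if c.id not in reachable:
                report.add("unreachable_consumer", f"consumer {c.id} has no path to any resource")
    return report
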