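"""Parameter-file, node and matrix CSV readers, and the sweep output writer.

The parameter file is a two-column ``key,value`` CSV whose keys follow the
simulator's canonical vocabulary (``topology``, ``pNoConnection``,
``noConnection``, ``resourcesFile``, ``planeMaxCoords``, ``sphereR``,
``nBranchPoints``, ``nConsumers``, ``useStrength``, ``strengthExponent``,
``manualNetwork``, ``randomConsumers``, ``consumersFile``, ``matrixFile``,
``branchPointsFile``, ``outputCSV``).  File paths are resolved relative to
the parameter file's directory.

Connection-matrix semantics: the matrix is square and symmetric over the
node order (resources, consumers, branch points); an entry equal to the
``noConnection`` placeholder means "no link", any other entry is the link
strength, and link lengths come from Euclidean distance between the
endpoint coordinates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Link,
    Network,
    Node,
    NodeRole,
    TopologyShape,
    TopologySpec,
)
from .generators import (
    GeneratorParams,
    calibrate_resource_potential,
    sample_point,
)
from .solver import Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "FormatError",
    "PARAMETER_KEYS",
    "ParameterFile",
    "read_parameters",
    "read_nodes",
    "read_matrix",
    "build_network",
    "write_output",
    "read_output",
]

#: Pinned float format for output CSVs (reproducible modulo nothing).
FLOAT_FORMAT = "%.12g"

PARAMETER_KEYS = (
    "topology",
    "pNoConnection",
    "noConnection",
    "resourcesFile",
    "planeMaxCoords",
    "sphereR",
    "nBranchPoints",
    "nConsumers",
    "useStrength",
    "strengthExponent",
    "manualNetwork",
    "randomConsumers",
    "consumersFile",
    "matrixFile",
    "branchPointsFile",
    "outputCSV",
)


class ConfigError(ValueError):
    """Missing, unknown or contradictory parameter-file entries."""


class FormatError(ValueError):
    """Malformed node or matrix CSV."""


@dataclass
class ParameterFile:
    """Validated simulation parameters (one field per canonical key)."""

    topology: TopologyShape
    pNoConnection: float = 0.8
    noConnection: float = -1.0
    resourcesFile: Path | None = None
    planeMaxCoords: float | None = None
    sphereR: float | None = None
    nBranchPoints: int = 0
    nConsumers: int = 20
    useStrength: bool = False
    strengthExponent: float = 2.0
    manualNetwork: bool = False
    randomConsumers: bool = True
    consumersFile: Path | None = None
    matrixFile: Path | None = None
    branchPointsFile: Path | None = None
    outputCSV: Path | None = None

    def topology_spec(self) -> TopologySpec:
        if self.topology is TopologyShape.PLANE:
            if self.planeMaxCoords is None:
                raise ConfigError("topology=PLANE requires planeMaxCoords")
            return TopologySpec(self.topology, self.planeMaxCoords)
        if self.sphereR is None:
            raise ConfigError(f"topology={self.topology.value} requires sphereR")
        return TopologySpec(self.topology, self.sphereR)


def _parse_bool(token: str, key: str) -> bool:
    t = token.strip().upper()
    if t == "TRUE":
        return True
    if t == "FALSE":
        return False
    raise ConfigError(f"{key}: expected TRUE or FALSE, got {token!r}")


def _parse_plane_coords(token: str) -> float:
    parts = token.split(";")
    if len(parts) != 2:
        raise ConfigError(f"planeMaxCoords must be a semicolon-separated pair, got {token!r}")
    try:
        x, y = (float(p) for p in parts)
    except ValueError as exc:
        raise ConfigError(f"planeMaxCoords: {exc}") from exc
    if x != y:
        raise ConfigError(
            f"only square planes are supported; planeMaxCoords gave {x} x {y}"
        )
    return x


def read_parameters(path: str | Path) -> ParameterFile:
    """Read and validate a key,value parameter CSV.

    Unknown keys are rejected; required keys are enforced per mode (e.g.
    ``matrixFile`` is required iff ``manualNetwork`` is TRUE).  Relative
    file paths resolve against the parameter file's directory.
    """
    path = Path(path)
    raw: dict[str, str] = {}
    problems: list[str] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] in (
                ["parameter", "value"],
                ["key", "value"],
            ):
                continue
            if len(row) < 2:
                problems.append(f"line {lineno}: expected 'key,value', got {row!r}")
                continue
            key, value = row[0].strip(), row[1].strip()
            if key not in PARAMETER_KEYS:
                problems.append(f"line {lineno}: unknown parameter {key!r}")
                continue
            raw[key] = value
    if problems:
        raise ConfigError("; ".join(problems))

    def _path(key: str) -> Path | None:
        if key not in raw or not raw[key]:
            return None
        p = Path(raw[key])
        return p if p.is_absolute() else path.parent / p

    try:
        shape = TopologyShape(raw.get("topology", "PLANE"))
    except ValueError as exc:
        raise ConfigError(f"topology: {exc}") from exc

    def _float(key: str, default: float | None) -> float | None:
        if key not in raw:
            return default
        try:
            return float(raw[key])
        except ValueError as exc:
            raise ConfigError(f"{key}: {exc}") from exc

    params = ParameterFile(
        topology=shape,
        pNoConnection=_float("pNoConnection", 0.8),
        noConnection=_float("noConnection", -1.0),
        resourcesFile=_path("resourcesFile"),
        planeMaxCoords=(
            _parse_plane_coords(raw["planeMaxCoords"]) if "planeMaxCoords" in raw else None
        ),
        sphereR=_float("sphereR", None),
        nBranchPoints=int(_float("nBranchPoints", 0)),
        nConsumers=int(_float("nConsumers", 20)),
        useStrength=_parse_bool(raw.get("useStrength", "FALSE"), "useStrength"),
        strengthExponent=_float("strengthExponent", 2.0),
        manualNetwork=_parse_bool(raw.get("manualNetwork", "FALSE"), "manualNetwork"),
        randomConsumers=_parse_bool(raw.get("randomConsumers", "TRUE"), "randomConsumers"),
        consumersFile=_path("consumersFile"),
        matrixFile=_path("matrixFile"),
        branchPointsFile=_path("branchPointsFile"),
        outputCSV=_path("outputCSV"),
    )

    contradictions = []
    if params.manualNetwork and params.matrixFile is None:
        contradictions.append("manualNetwork=TRUE requires matrixFile")
    if not params.randomConsumers and params.consumersFile is None:
        contradictions.append("randomConsumers=FALSE requires consumersFile")
    if params.topology is TopologyShape.PLANE and params.planeMaxCoords is None:
        contradictions.append("topology=PLANE requires planeMaxCoords")
    if params.topology is not TopologyShape.PLANE and params.sphereR is None:
        contradictions.append(f"topology={params.topology.value} requires sphereR")
    if contradictions:
        raise ConfigError("; ".join(contradictions))
    return params


def read_nodes(path: str | Path, role: NodeRole, ndim: int, start_id: int = 0) -> list[Node]:
    """Read node locations (and, for resources, potentials) from CSV.

    Expects a header with coordinate columns ``x,y[,z]`` and, for resource
    files, a ``potential`` column.  Malformed rows raise with their line
    number.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    coord_cols = ["x", "y", "z"][:ndim]
    missing = [c for c in coord_cols if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing coordinate column(s) {missing}")
    if role is NodeRole.RESOURCE and "potential" not in cols:
        raise FormatError(f"{path}: resource file needs a 'potential' column")
    nodes: list[Node] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            coords = np.array([float(row[c]) for c in coord_cols])
            if not np.all(np.isfinite(coords)):
                raise ValueError("non-finite coordinate")
            potential = None
            if role is NodeRole.RESOURCE:
                potential = float(row["potential"])
                if not np.isfinite(potential):
                    raise ValueError("non-finite potential")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        nodes.append(Node(start_id + len(nodes), role, coords, potential=potential))
    return nodes


def read_matrix(path: str | Path, no_connection: float = -1.0) -> np.ndarray:
    """Read a square, symmetric connection matrix CSV (no header).

    Entries equal to ``no_connection`` mean "no link"; asymmetric or
    non-square input is a format error.
    """
    m = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: connection matrix is not square (shape {m.shape})")
    if not np.array_equal(m, m.T):
        bad = np.argwhere(m != m.T)[0]
        raise FormatError(
            f"{path}: asymmetric entries at ({bad[0]},{bad[1]}) / ({bad[1]},{bad[0]})"
        )
    return m


def build_network(params: ParameterFile, seed: int = 0) -> Network:
    """Assemble a network from a validated parameter file.

    Node order (and therefore matrix order) is resources, consumers, branch
    points.  With ``manualNetwork`` FALSE, links are drawn randomly per
    ``pNoConnection`` via the random generator; consumers are placed
    randomly unless a consumers file is given.
    """
    topo = params.topology_spec()
    rng = np.random.default_rng(seed)

    if params.resourcesFile is not None:
        resources = read_nodes(params.resourcesFile, NodeRole.RESOURCE, topo.ndim)
    else:
        resources = [Node(0, NodeRole.RESOURCE, sample_point(topo, rng), potential=1.0)]
    nid = len(resources)

    if params.randomConsumers:
        consumers = [
            Node(nid + k, NodeRole.CONSUMER, sample_point(topo, rng))
            for k in range(params.nConsumers)
        ]
    else:
        consumers = read_nodes(params.consumersFile, NodeRole.CONSUMER, topo.ndim, start_id=nid)
    nid += len(consumers)

    branch_points: list[Node] = []
    if params.branchPointsFile is not None:
        branch_points = read_nodes(
            params.branchPointsFile, NodeRole.BRANCH_POINT, topo.ndim, start_id=nid
        )
    elif params.nBranchPoints:
        branch_points = [
            Node(nid + k, NodeRole.BRANCH_POINT, sample_point(topo, rng))
            for k in range(params.nBranchPoints)
        ]

    nodes = resources + consumers + branch_points

    if params.manualNetwork:
        m = read_matrix(params.matrixFile, params.noConnection)
        if m.shape[0] != len(nodes):
            raise FormatError(
                f"connection matrix is {m.shape[0]}x{m.shape[0]} but the network has "
                f"{len(nodes)} nodes"
            )
        links = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if m[i, j] == params.noConnection:
                    continue
                length = float(np.linalg.norm(nodes[i].coords - nodes[j].coords))
                links.append(Link(nodes[i].id, nodes[j].id, length, strength=float(m[i, j])))
        network = Network(nodes, links, topo)
    else:
        links = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = nodes[i], nodes[j]
                if a.role is NodeRole.RESOURCE and b.role is NodeRole.RESOURCE:
                    continue
                if rng.uniform() >= 1.0 - params.pNoConnection:
                    continue
                length = float(np.linalg.norm(a.coords - b.coords))
                if length <= 0:
                    continue
                links.append(Link(a.id, b.id, length))
        network = Network(nodes, links, topo)

    if params.resourcesFile is None:
        # no supplied potentials: calibrate so the power peak is mid-sweep
        calibrate_resource_potential(network)
    log.info(
        "built network: %d resources, %d consumers, %d branch points, %d links",
        len(resources), len(consumers), len(branch_points), len(network.links),
    )
    return network


def write_output(trajectory: Trajectory, network: Network, path: str | Path) -> None:
    """Write the sweep output CSV: one row per demand step.

    Canonical column order: ``demand``; per-resource potential ``V_R<i>``
    and power production ``P_R<i>``; per-consumer potential ``V_C<i>`` and
    power consumption ``P_C<i>``; ``total_link_length`` (constant across
    rows).  Floats are pinned to a fixed precision for reproducibility.
    """
    total_length = network.total_link_length()
    rows = []
    for rec in trajectory:
        row: dict[str, float] = {"demand": rec.demand}
        for i, r in enumerate(network.resources):
            row[f"V_R{i}"] = r.potential
            row[f"P_R{i}"] = rec.resource_output[i]
        for i, v in enumerate(rec.consumer_potentials):
            row[f"V_C{i}"] = v
            row[f"P_C{i}"] = rec.consumer_power[i]
        row["total_link_length"] = total_length
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    log.info("wrote %d sweep rows to %s", len(rows), path)


def read_output(path: str | Path) -> pd.DataFrame:
    """Read a sweep output CSV back into a frame (round-trip counterpart)."""
    return pd.read_csv(path)
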