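"""Load-flow solver: nodal potentials, link flows, and the demand sweep.

The nodal equations are the weighted-Laplacian (Kirchhoff) balance: at every
non-resource node, the net conducted inflow equals the node's demand
(consumers draw a fixed specified flow; branch points draw nothing), with
resource potentials as Dirichlet boundary conditions.  Two solution paths
are provided:

* :func:`direct_solve` — one-shot sparse linear solve; exact to solver
  precision and used as the oracle throughout the test suite.
* :func:`solve_fixed_demand` — the iterative load-flow scheme: invert the
  conductance (Jacobian) matrix for the mismatch between specified and
  received flow at every demand node, adjust potentials to counter the
  mismatch, and repeat until the worst mismatch is below the threshold
  (default 0.001 flow units).  For this linear flow law the correction
  step is Newton's method and lands on the direct solution in one update;
  the loop structure is kept because the mismatch threshold is part of
  the method's contract.

Because link strengths are fixed during a sweep, the solved potentials are
affine in the per-consumer demand: V(I) = V0 − I·W, where V0 is the
zero-demand solution and W the unit-demand response.  :func:`sweep`
exploits this — two sparse solves per network, then every grid step is an
exact evaluation of the same linear system (verified against both solve
paths in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import (
    DemandSpec,
    Network,
    NetworkValidationError,
    NodeRole,
    validate,
)

__all__ = [
    "SolverConfig",
    "SweepRecord",
    "Trajectory",
    "SingularSystemError",
    "ConvergenceError",
    "assemble_conductance",
    "solve_fixed_demand",
    "direct_solve",
    "sweep",
    "find_max_power",
]


class SingularSystemError(ValueError):
    """The nodal system has no unique solution (disconnected demand nodes)."""


class ConvergenceError(RuntimeError):
    """The iterative solver failed to meet the mismatch threshold."""


@dataclass(frozen=True)
class SolverConfig:
    """Iterative-solver settings.

    ``tolerance`` is the flow-mismatch threshold (default 0.001 flow units);
    iteration stops when every demand node's received flow is within it.
    """

    tolerance: float = 1e-3
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class _NodalSystem:
    """Indexing and matrices for the reduced (non-resource) nodal equations."""

    unknown_ids: list[int]          # consumer + branch-point node ids, in node order
    resource_ids: list[int]
    laplacian: sp.csc_matrix        # conductance among unknowns
    boundary: sp.csc_matrix         # coupling unknowns -> resources
    resource_potentials: np.ndarray
    demand_mask: np.ndarray         # True where the unknown is a consumer


def _build_system(network: Network) -> _NodalSystem:
    report = validate(network)
    if not report.ok:
        unreachable = [f for f in report.findings if f.kind == "unreachable_consumer"]
        if unreachable and len(unreachable) == len(report.findings):
            raise SingularSystemError("; ".join(f.message for f in unreachable))
        raise NetworkValidationError(
            "network failed validation: "
            + "; ".join(f.message for f in report.findings)
        )
    unknown_ids = [n.id for n in network.nodes if n.role is not NodeRole.RESOURCE]
    resource_ids = [n.id for n in network.nodes if n.role is NodeRole.RESOURCE]
    u_index = {nid: k for k, nid in enumerate(unknown_ids)}
    r_index = {nid: k for k, nid in enumerate(resource_ids)}
    nu, nr = len(unknown_ids), len(resource_ids)

    diag = np.zeros(nu)
    rows_l, cols_l, vals_l = [], [], []
    rows_b, cols_b, vals_b = [], [], []
    for link in network.links:
        g = 1.0 / link.resistance
        a, b = link.node_a, link.node_b
        a_u, b_u = a in u_index, b in u_index
        if a_u:
            diag[u_index[a]] += g
        if b_u:
            diag[u_index[b]] += g
        if a_u and b_u:
            rows_l += [u_index[a], u_index[b]]
            cols_l += [u_index[b], u_index[a]]
            vals_l += [-g, -g]
        elif a_u:
            rows_b.append(u_index[a]); cols_b.append(r_index[b]); vals_b.append(g)
        elif b_u:
            rows_b.append(u_index[b]); cols_b.append(r_index[a]); vals_b.append(g)
        # resource-resource links carry no information for the reduced system

    lap = sp.csc_matrix(
        (np.concatenate([vals_l, diag]),
         (np.concatenate([rows_l, np.arange(nu)]).astype(int),
          np.concatenate([cols_l, np.arange(nu)]).astype(int))),
        shape=(nu, nu),
    )
    bnd = sp.csc_matrix((vals_b, (rows_b, cols_b)), shape=(nu, nr))
    v_r = np.array([network.node(i).potential for i in resource_ids], dtype=float)
    demand_mask = np.array(
        [network.node(i).role is NodeRole.CONSUMER for i in unknown_ids]
    )
    return _NodalSystem(unknown_ids, resource_ids, lap, bnd, v_r, demand_mask)


def assemble_conductance(network: Network) -> sp.csc_matrix:
    """Conductance (Jacobian) matrix over the non-resource nodes.

    Symmetric weighted-Laplacian structure: off-diagonal entries are −1/R
    for linked pairs, diagonals are the sum of all incident conductances
    (links to resources included, which is how the fixed-potential boundary
    enters the system).
    """
    return _build_system(network).laplacian


def _potentials_vector(network: Network, sys_: _NodalSystem, v_u: np.ndarray) -> np.ndarray:
    """Full node-ordered potential vector from the unknown-block solution."""
    v = np.empty(len(network.nodes))
    pos = {n.id: i for i, n in enumerate(network.nodes)}
    for nid, val in zip(sys_.resource_ids, sys_.resource_potentials):
        v[pos[nid]] = val
    for nid, val in zip(sys_.unknown_ids, v_u):
        v[pos[nid]] = val
    return v


@dataclass
class SweepRecord:
    """One demand level's solved state.

    Per-link quantities are derived lazily from the potentials so that long
    sweeps stay cheap to hold in memory; ``link_flows[k]`` is signed positive
    from ``links[k].node_a`` towards ``node_b``.
    """

    network: Network
    demand: float
    potentials: np.ndarray  # ordered as network.nodes

    @cached_property
    def _index(self) -> dict[int, int]:
        return {n.id: i for i, n in enumerate(self.network.nodes)}

    def potential_of(self, node_id: int) -> float:
        return float(self.potentials[self._index[node_id]])

    @cached_property
    def consumer_potentials(self) -> np.ndarray:
        idx = [self._index[n.id] for n in self.network.consumers]
        return self.potentials[idx]

    @cached_property
    def consumer_power(self) -> np.ndarray:
        return self.demand * self.consumer_potentials

    @cached_property
    def link_flows(self) -> np.ndarray:
        ia = np.array([self._index[l.node_a] for l in self.network.links])
        ib = np.array([self._index[l.node_b] for l in self.network.links])
        r = np.array([l.resistance for l in self.network.links])
        if len(self.network.links) == 0:
            return np.empty(0)
        return (self.potentials[ia] - self.potentials[ib]) / r

    @cached_property
    def link_losses(self) -> np.ndarray:
        r = np.array([l.resistance for l in self.network.links])
        return self.link_flows**2 * r

    @cached_property
    def total_power(self) -> float:
        return float(self.consumer_power.sum())

    @cached_property
    def resource_output(self) -> np.ndarray:
        """Power injected by each resource: V_R times its net outflow."""
        out = np.zeros(len(self.network.resources))
        r_pos = {n.id: i for i, n in enumerate(self.network.resources)}
        flows = self.link_flows
        for k, link in enumerate(self.network.links):
            if link.node_a in r_pos:
                out[r_pos[link.node_a]] += flows[k] * self.potential_of(link.node_a)
            if link.node_b in r_pos:
                out[r_pos[link.node_b]] -= flows[k] * self.potential_of(link.node_b)
        return out

    @cached_property
    def mean_potential_ratio(self) -> float:
        """Mean consumer potential over mean resource potential."""
        v_r = np.mean([n.potential for n in self.network.resources])
        return float(self.consumer_potentials.mean() / v_r)


class Trajectory:
    """Ordered sweep records over strictly increasing demand levels."""

    DEMAND_CEILING = "demand_ceiling"
    NEGATIVE_POWER = "negative_power"

    def __init__(self, records: list[SweepRecord], termination: str) -> None:
        if not records:
            raise ValueError("empty trajectory")
        self.records = records
        self.termination = termination

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SweepRecord:
        return self.records[i]

    @property
    def network(self) -> Network:
        return self.records[0].network

    @cached_property
    def demands(self) -> np.ndarray:
        return np.array([r.demand for r in self.records])

    @cached_property
    def total_power(self) -> np.ndarray:
        return np.array([r.total_power for r in self.records])

    @cached_property
    def ratios(self) -> np.ndarray:
        return np.array([r.mean_potential_ratio for r in self.records])


def direct_solve(network: Network, i_c: float) -> SweepRecord:
    """One-shot linear solve of the nodal equations at demand ``i_c``.

    Exact to sparse-solver precision; serves as the independent oracle for
    the iterative path.
    """
    sys_ = _build_system(network)
    rhs = sys_.boundary @ sys_.resource_potentials - i_c * sys_.demand_mask
    v_u = _solve_checked(sys_, rhs)
    return SweepRecord(network, i_c, _potentials_vector(network, sys_, v_u))


def _solve_checked(sys_: _NodalSystem, rhs: np.ndarray) -> np.ndarray:
    if sys_.laplacian.shape[0] == 0:
        return np.empty(0)
    # a row with zero absolute sum is a floating node
    row_sums = np.asarray(np.abs(sys_.laplacian).sum(axis=1)).ravel()
    if np.any(row_sums == 0):
        bad = [sys_.unknown_ids[i] for i in np.nonzero(row_sums == 0)[0]]
        raise SingularSystemError(f"isolated non-resource nodes: {bad}")
    try:
        v_u = spla.spsolve(sys_.laplacian, rhs)
    except Exception as exc:  # umfpack/superlu raise various singular errors
        raise SingularSystemError(str(exc)) from exc
    if not np.all(np.isfinite(v_u)):
        raise SingularSystemError(
            "singular nodal system (consumers not connected to any resource)"
        )
    return np.atleast_1d(v_u)


def solve_fixed_demand(
    network: Network, i_c: float, config: SolverConfig | None = None
) -> SweepRecord:
    """Iterative load flow at a fixed per-consumer demand.

    Starting from a flat potential profile, each iteration computes the
    mismatch between specified and received flow at every consumer (and the
    net imbalance at branch points), solves the conductance system for the
    counteracting potential adjustment, and applies it; iteration ends when
    the worst mismatch is inside ``config.tolerance``.
    """
    if i_c <= 0:
        raise ValueError(f"per-consumer demand must be positive, got {i_c}")
    config = config or SolverConfig()
    sys_ = _build_system(network)
    specified = i_c * sys_.demand_mask
    v_u = np.full(len(sys_.unknown_ids), float(sys_.resource_potentials.mean()))
    lu = spla.splu(sys_.laplacian.tocsc()) if sys_.laplacian.shape[0] else None
    worst = np.inf
    for _ in range(config.max_iterations):
        received = sys_.boundary @ sys_.resource_potentials - sys_.laplacian @ v_u
        mismatch = received - specified
        worst = float(np.max(np.abs(mismatch))) if mismatch.size else 0.0
        if worst <= config.tolerance:
            return SweepRecord(network, i_c, _potentials_vector(network, sys_, v_u))
        v_u = v_u + lu.solve(mismatch)
    raise ConvergenceError(
        f"no convergence in {config.max_iterations} iterations; worst mismatch {worst:g}"
    )


def sweep(
    network: Network,
    demand: DemandSpec | None = None,
    config: SolverConfig | None = None,
) -> Trajectory:
    """Sweep per-consumer demand and record the solved state at each step.

    Steps run from ``demand.start`` upward by ``demand.step`` until either
    the ceiling ``demand.stop`` is reached or total network power turns
    negative; the first negative-power record is included and the
    termination reason recorded.

    Link strengths are fixed during the sweep, so the potentials at demand
    I are V0 − I·W with V0 the zero-demand solution and W the unit-demand
    response; both come from one factorised system, and every grid record
    is an exact solution of the nodal equations at its demand.
    """
    demand = demand or DemandSpec()
    sys_ = _build_system(network)
    rhs0 = sys_.boundary @ sys_.resource_potentials
    v0 = _solve_checked(sys_, rhs0)
    w = _solve_checked(sys_, sys_.demand_mask.astype(float))

    grid = demand.grid()
    full0 = _potentials_vector(network, sys_, v0)
    pos = {n.id: i for i, n in enumerate(network.nodes)}
    # demand response of the full vector: zero at resources, w at unknowns
    fullw = np.zeros(len(network.nodes))
    for nid, val in zip(sys_.unknown_ids, w):
        fullw[pos[nid]] = val

    c_idx = [pos[n.id] for n in network.consumers]
    # total power P(I) = I * sum_c (v0_c - I*w_c): find first negative-power step
    sum_v0 = full0[c_idx].sum()
    sum_w = fullw[c_idx].sum()
    p_grid = grid * (sum_v0 - grid * sum_w)
    neg = np.nonzero(p_grid < 0)[0]
    if neg.size:
        grid = grid[: neg[0] + 1]
        termination = Trajectory.NEGATIVE_POWER
    else:
        termination = Trajectory.DEMAND_CEILING

    records = [
        SweepRecord(network, float(i), full0 - i * fullw) for i in grid
    ]
    return Trajectory(records, termination)


def find_max_power(trajectory: Trajectory) -> SweepRecord:
    """The sweep record with maximal total network power.

    Ties break toward the lower demand (first occurrence on the grid).
    """
    i = int(np.argmax(trajectory.total_power))
    return trajectory[i]
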