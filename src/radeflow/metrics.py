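"""Inequality metrics: effective resistance, σ identities, and figure tables.

The central quantity is the per-consumer *effective resistance*

    R_Ei = (V̄_R − V_Ci) / I_i,

the flow-normalised potential drop from the (mean) resource to consumer i
along whatever paths connect them.  For fixed-strength networks R_Ei is
flow-invariant, and the spreads of consumer potential and consumer power
obey exact identities

    σ_VC = σ_RE · I,        σ_PC = σ_RE · I²,

which is why the standard deviation (not a relative index like Gini) is the
inequality measure of choice here: it carries the units of the mean and
grows with absolute disparity even when relative shares are unchanged.

All standard deviations use the population (divide-by-n) convention by
default; the identities above are exact algebraic statements only under a
single consistent convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Network, NodeRole
from .solver import SweepRecord, Trajectory, find_max_power

__all__ = [
    "MetricsRecord",
    "effective_resistance",
    "inequality_stats",
    "sigma_re",
    "sigma_slope",
    "normalise_density",
    "level_power_series",
    "potential_distribution",
    "gini",
    "trajectory_metrics",
]


def _std(x: np.ndarray, sample: bool = False) -> float:
    return float(np.std(np.asarray(x, dtype=float), ddof=1 if sample else 0))


def effective_resistance(record: SweepRecord, network: Network | None = None) -> np.ndarray:
    """Per-consumer effective resistance at a solved record.

    Uses the mean resource potential, which extends the definition to
    multi-resource networks; for a consumer linked directly (and only) to
    the resource this reduces to the link resistance.
    """
    net = network or record.network
    if record.demand <= 0:
        raise ValueError("effective resistance is undefined at zero demand")
    v_r = float(np.mean([n.potential for n in net.resources]))
    return (v_r - record.consumer_potentials) / record.demand


def sigma_re(record: SweepRecord, sample: bool = False) -> float:
    """Standard deviation of the per-consumer effective resistances."""
    return _std(effective_resistance(record), sample=sample)


@dataclass(frozen=True)
class MetricsRecord:
    """Inequality statistics of one solved sweep record."""

    demand: float
    sigma_vc: float
    sigma_pc: float
    sigma_re: float
    mean_ratio: float
    total_power: float


def inequality_stats(record: SweepRecord, sample: bool = False) -> MetricsRecord:
    """σ of consumer potential and power, and the mean-potential ratio."""
    return MetricsRecord(
        demand=record.demand,
        sigma_vc=_std(record.consumer_potentials, sample=sample),
        sigma_pc=_std(record.consumer_power, sample=sample),
        sigma_re=sigma_re(record, sample=sample),
        mean_ratio=record.mean_potential_ratio,
        total_power=record.total_power,
    )


def sigma_slope(trajectory: Trajectory, sample: bool = False) -> float:
    """Origin-constrained least-squares slope of σ_PC against demand squared.

    For fixed-strength networks this slope equals σ_RE exactly — the σ_PC
    identity in linear form — so slope/σ_RE is a stringent end-to-end check
    of the whole solve-and-measure pipeline.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least two sweep records to fit a slope")
    x = trajectory.demands**2
    y = np.array([_std(r.consumer_power, sample=sample) for r in trajectory])
    return float((x * y).sum() / (x * x).sum())


def normalise_density(
    trajectory: Trajectory,
    ratios: tuple[float, ...] = (0.75, 0.5, 0.25),
    reference_ratio: float = 0.75,
) -> dict[float, np.ndarray]:
    """Consumer-power samples at chosen potential ratios, jointly normalised.

    For each requested ratio of mean consumer to mean resource potential,
    the sweep record with the nearest ratio is selected and its consumer
    powers are centred on their own mean and scaled by the consumer-power
    standard deviation at the *reference* ratio (default 0.75) — so the
    reference sample has σ = 1 and the widening of the others shows how
    inequality grows as flow pushes the network past its power peak.
    Degenerate zero-σ networks normalise to exact zeros.
    """
    traj_ratios = trajectory.ratios
    lo, hi = float(traj_ratios.min()), float(traj_ratios.max())
    wanted = set(ratios) | {reference_ratio}
    for r in wanted:
        if not (lo - 1e-9 <= r <= hi + 1e-9):
            raise ValueError(
                f"ratio {r} outside the trajectory's range [{lo:.4f}, {hi:.4f}]"
            )
    pick = {r: trajectory[int(np.argmin(np.abs(traj_ratios - r)))] for r in wanted}
    ref_sigma = _std(pick[reference_ratio].consumer_power)
    out: dict[float, np.ndarray] = {}
    for r in ratios:
        p = pick[r].consumer_power
        centred = p - p.mean()
        out[r] = centred / ref_sigma if ref_sigma > 0 else np.zeros_like(centred)
    return out


def level_power_series(trajectory: Trajectory, network: Network | None = None) -> pd.DataFrame:
    """Per-level mean consumer power across the sweep, for branched families.

    Returns a tidy frame with columns ``level``, ``demand``, ``mean_power``,
    ``relative_power`` (normalised by the maximum per-level mean power in
    the whole table), ``relative_demand`` (normalised by the maximum
    demand), and ``at_network_peak`` flagging the demand of network-wide
    maximum power.  Levels are the branched families' depth labels
    (0 = consumers nearest the resource).
    """
    net = network or trajectory.network
    levels = sorted({n.level for n in net.consumers if n.level is not None})
    if not levels:
        raise ValueError("network has no level labels; not a branched family")
    consumer_levels = np.array(
        [n.level if n.level is not None else -1 for n in net.consumers]
    )
    peak_demand = find_max_power(trajectory).demand
    rows = []
    for rec in trajectory:
        for lvl in levels:
            rows.append(
                {
                    "level": lvl,
                    "demand": rec.demand,
                    "mean_power": rec.consumer_power[consumer_levels == lvl].mean(),
                }
            )
    df = pd.DataFrame(rows)
    df["relative_power"] = df["mean_power"] / df["mean_power"].max()
    df["relative_demand"] = df["demand"] / df["demand"].max()
    df["at_network_peak"] = df["demand"] == peak_demand
    return df


def potential_distribution(
    record: SweepRecord, decimals: int = 6, bins: int | None = None
) -> pd.Series:
    """Frequency table of consumer potentials at one solved record.

    With ``bins=None`` potentials are grouped by rounded value (surfacing
    the level-quantised structure of branched networks, where the number of
    distinct potentials equals the number of levels); with ``bins`` set, an
    ordinary histogram is returned instead.
    """
    v = record.consumer_potentials
    if bins is not None:
        counts, edges = np.histogram(v, bins=bins)
        mid = 0.5 * (edges[:-1] + edges[1:])
        return pd.Series(counts, index=mid, name="frequency")
    vals, counts = np.unique(np.round(v, decimals), return_counts=True)
    return pd.Series(counts, index=vals, name="frequency")


def gini(values: np.ndarray) -> float:
    """Gini coefficient (convenience only; scale-blind by construction).

    A relative index: inflating every value by the same factor leaves it
    unchanged even though absolute spread grows, which is exactly why the
    σ-based measures above are preferred for this model.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0 or np.all(v == 0):
        return 0.0
    cum = np.cumsum(v)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def trajectory_metrics(trajectory: Trajectory, sample: bool = False) -> pd.DataFrame:
    """Inequality statistics of every record, as a tidy frame."""
    rows = [inequality_stats(r, sample=sample).__dict__ for r in trajectory]
    return pd.DataFrame(rows)
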