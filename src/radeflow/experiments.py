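"""Experiment drivers: regenerate the study's figure-level analyses.

Each driver simulates fresh networks at a configurable scale, writes the
underlying data tables as CSV, and (optionally) renders a matplotlib
figure from those same tables.  Assertions and acceptance checks always
read the tables, never the rendered images.

Available experiments:

* ``max-power-ratio`` — six example networks (random links on plane /
  sphere / sphere-surface topologies plus a radial burst); total power
  against the mean consumer-to-resource potential ratio, peaking at 0.5,
  and the slope-of-σ_PC-vs-I² identity against σ_RE.
* ``power-dispersion`` — normalised consumer-power distributions for the
  same networks at potential ratios 0.75 / 0.50 / 0.25.
* ``evolved-branching`` — per-stage power trajectories while a jittered
  radial burst is evolved into a self-similar branching tree.
* ``potential-distribution`` — frequency distribution of consumer
  potentials at maximum network power for the fully branched network.
* ``level-power`` — per-level relative consumer power against relative
  demand for the fully branched network, with the network-wide peak marked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Network, TopologyShape
from .generators import (
    GeneratorParams,
    apply_strength_rule,
    calibrate_resource_potential,
    evolved_branching,
    evolved_branching_base,
    fully_branched,
    radial_burst,
    random_network,
)
from .metrics import (
    level_power_series,
    normalise_density,
    potential_distribution,
    sigma_re,
    sigma_slope,
    trajectory_metrics,
)
from .solver import Trajectory, find_max_power, sweep

log = logging.getLogger(__name__)

__all__ = ["EXPERIMENTS", "example_networks", "run_experiment"]


def example_networks(seed: int = 0, scale: float = 1.0) -> dict[str, Network]:
    """The six example networks used for the framework illustrations.

    Five random spatial networks spanning the three topologies (plane,
    sphere, sphere surface; one with two equal-potential resources, one
    denser plane) plus an idealised radial burst.  ``scale`` multiplies the
    consumer counts (floor of 4); seeds derive deterministically from
    ``seed``.
    """
    def n(base: int) -> int:
        return max(4, int(round(base * scale)))

    specs = {
        "plane": GeneratorParams(
            n_consumers=n(30), shape=TopologyShape.PLANE, p_no_connection=0.8, seed=seed * 6 + 1
        ),
        "sphere": GeneratorParams(
            n_consumers=n(30), shape=TopologyShape.SPHERE, p_no_connection=0.8, seed=seed * 6 + 2
        ),
        "sphere_surface": GeneratorParams(
            n_consumers=n(30),
            shape=TopologyShape.SPHERE_SURFACE,
            p_no_connection=0.8,
            seed=seed * 6 + 3,
        ),
        "plane_dense": GeneratorParams(
            n_consumers=n(60), shape=TopologyShape.PLANE, p_no_connection=0.9, seed=seed * 6 + 4
        ),
        "sphere_two_resources": GeneratorParams(
            n_consumers=n(20),
            n_resources=2,
            shape=TopologyShape.SPHERE,
            p_no_connection=0.7,
            seed=seed * 6 + 5,
        ),
    }
    nets = {name: random_network(p) for name, p in specs.items()}
    nets["radial_burst"] = radial_burst(n(64))
    return nets


def _sweep_all(networks: dict[str, Network]) -> dict[str, Trajectory]:
    return {name: sweep(net) for name, net in networks.items()}


def _maybe_figure(fn, path: Path, make_figures: bool) -> None:
    if not make_figures:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = fn(plt)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    log.info("figure written to %s", path)


def _run_max_power_ratio(seed: int, scale: float, outdir: Path, make_figures: bool):
    networks = example_networks(seed, scale)
    trajectories = _sweep_all(networks)
    curves, summary = [], []
    for name, traj in trajectories.items():
        m = trajectory_metrics(traj)
        m.insert(0, "network", name)
        m["relative_power"] = m["total_power"] / m["total_power"].max()
        curves.append(m)
        peak = find_max_power(traj)
        s_re = sigma_re(traj[0])
        slope = sigma_slope(traj)
        summary.append(
            {
                "network": name,
                "peak_demand": peak.demand,
                "peak_ratio": peak.mean_potential_ratio,
                "sigma_re": s_re,
                "sigma_pc_slope": slope,
                "slope_over_sigma_re": slope / s_re if s_re > 0 else np.nan,
                "termination": traj.termination,
            }
        )
    curves_df = pd.concat(curves, ignore_index=True)
    summary_df = pd.DataFrame(summary)
    curves_df.to_csv(outdir / "max_power_ratio_curves.csv", index=False)
    summary_df.to_csv(outdir / "max_power_ratio_summary.csv", index=False)
    for row in summary:
        log.info(
            "%s: peak at demand %.1f, ratio %.4f, slope/sigma_RE %.8f",
            row["network"], row["peak_demand"], row["peak_ratio"],
            row["slope_over_sigma_re"],
        )

    def draw(plt):
        fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
        for name, grp in curves_df.groupby("network"):
            axes[0].plot(grp["mean_ratio"], grp["relative_power"], label=name, lw=1)
            axes[1].plot(grp["demand"] ** 2, grp["sigma_pc"], label=name, lw=1)
        axes[0].axvline(0.5, color="k", ls=":", lw=0.8)
        axes[0].set_xlabel("mean consumer / mean resource potential")
        axes[0].set_ylabel("relative total power")
        axes[0].invert_xaxis()
        axes[1].set_xlabel("demand$^2$")
        axes[1].set_ylabel(r"$\sigma_{P_C}$")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        return fig

    _maybe_figure(draw, outdir / "max_power_ratio.png", make_figures)
    return {"curves": curves_df, "summary": summary_df}


def _run_power_dispersion(seed: int, scale: float, outdir: Path, make_figures: bool):
    networks = example_networks(seed, scale)
    rows = []
    for name, net in networks.items():
        traj = sweep(net)
        samples = normalise_density(traj)
        for ratio, values in samples.items():
            for v in values:
                rows.append({"network": name, "ratio": ratio, "normalised_power": v})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "power_dispersion_samples.csv", index=False)

    def draw(plt):
        names = sorted(df["network"].unique())
        fig, axes = plt.subplots(len(names), 1, figsize=(7, 2 * len(names)), sharex=True)
        for ax, name in zip(np.atleast_1d(axes), names):
            sub = df[df["network"] == name]
            for ratio, grp in sub.groupby("ratio"):
                ax.hist(grp["normalised_power"], bins=30, alpha=0.5, label=f"ratio {ratio}")
            ax.set_ylabel(name, fontsize=7)
        np.atleast_1d(axes)[0].legend(fontsize=7)
        np.atleast_1d(axes)[-1].set_xlabel("normalised consumer power")
        fig.tight_layout()
        return fig

    _maybe_figure(draw, outdir / "power_dispersion.png", make_figures)
    return {"samples": df}


def _evolved_stage_networks(seed: int, scale: float, max_stage: int = 7):
    """Strength-ruled evolved-branching networks for every stage, with a
    common resource potential calibrated on the final (fully branched) stage."""
    exponent = int(np.clip(round(9 * scale), max_stage, 12))
    n_consumers = 2**exponent
    base = evolved_branching_base(n_consumers=n_consumers, seed=seed, resource_potential=1.0)
    stages = {}
    for stage in range(max_stage + 1):
        net = evolved_branching(base, stage, max_stage=max_stage)
        apply_strength_rule(net, exponent=2.0)
        stages[stage] = net
    calibrate_resource_potential(stages[max_stage], target_peak_demand=300.0)
    v_r = stages[max_stage].resources[0].potential
    for net in stages.values():
        for r in net.resources:
            r.potential = v_r
    return stages


def _run_evolved_branching(seed: int, scale: float, outdir: Path, make_figures: bool):
    stages = _evolved_stage_networks(seed, scale)
    rows, summary = [], []
    for stage, net in stages.items():
        traj = sweep(net)
        m = trajectory_metrics(traj)
        m.insert(0, "stage", stage)
        rows.append(m)
        summary.append(
            {
                "stage": stage,
                "total_link_length": net.total_link_length(),
                "max_power": float(m["total_power"].max()),
                "max_sigma_pc": float(m["sigma_pc"].max()),
            }
        )
    curves = pd.concat(rows, ignore_index=True)
    curves["relative_power"] = curves["total_power"] / curves["total_power"].max()
    summary_df = pd.DataFrame(summary)
    curves.to_csv(outdir / "evolved_branching_curves.csv", index=False)
    summary_df.to_csv(outdir / "evolved_branching_summary.csv", index=False)
    for row in summary:
        log.info(
            "stage %d: total link length %.1f, max power %.4g",
            row["stage"], row["total_link_length"], row["max_power"],
        )

    def draw(plt):
        fig, ax = plt.subplots(figsize=(7, 5))
        for stage, grp in curves.groupby("stage"):
            ax.plot(grp["mean_ratio"], grp["relative_power"], label=f"stage {stage}", lw=1)
        ax.set_xlabel("mean consumer / mean resource potential")
        ax.set_ylabel("relative total power")
        ax.invert_xaxis()
        ax.legend(fontsize=7)
        fig.tight_layout()
        return fig

    _maybe_figure(draw, outdir / "evolved_branching.png", make_figures)
    return {"curves": curves, "summary": summary_df}


def _branched_network(scale: float) -> Network:
    levels = int(np.clip(round(8 * scale), 2, 10))
    net = fully_branched(levels=levels, resource_potential=1.0)
    apply_strength_rule(net, exponent=2.0)
    return calibrate_resource_potential(net)


def _run_potential_distribution(seed: int, scale: float, outdir: Path, make_figures: bool):
    net = _branched_network(scale)
    traj = sweep(net)
    peak = find_max_power(traj)
    dist = potential_distribution(peak)
    df = dist.rename_axis("potential").reset_index()
    df.to_csv(outdir / "potential_distribution.csv", index=False)
    log.info(
        "peak at demand %.1f; %d distinct consumer potentials", peak.demand, len(df)
    )

    def draw(plt):
        fig, ax = plt.subplots(figsize=(6, 4.5))
        ax.loglog(df["potential"], df["frequency"], "o")
        ax.set_xlabel("consumer potential $V_C$")
        ax.set_ylabel("frequency")
        fig.tight_layout()
        return fig

    _maybe_figure(draw, outdir / "potential_distribution.png", make_figures)
    return {"distribution": df}


def _run_level_power(seed: int, scale: float, outdir: Path, make_figures: bool):
    net = _branched_network(scale)
    traj = sweep(net)
    df = level_power_series(traj, net)
    df.to_csv(outdir / "level_power.csv", index=False)
    peak_rel = df.loc[df["at_network_peak"], "relative_demand"].iloc[0]

    def draw(plt):
        fig, ax = plt.subplots(figsize=(6.5, 4.5))
        for lvl, grp in df.groupby("level"):
            ax.plot(grp["relative_demand"], grp["relative_power"], label=f"level {lvl}", lw=1)
        ax.axvline(peak_rel, color="k", lw=1)
        ax.set_xlabel("relative demand per consumer")
        ax.set_ylabel("relative consumer power")
        ax.legend(fontsize=7)
        fig.tight_layout()
        return fig

    _maybe_figure(draw, outdir / "level_power.png", make_figures)
    return {"series": df}


EXPERIMENTS = {
    "max-power-ratio": _run_max_power_ratio,
    "power-dispersion": _run_power_dispersion,
    "evolved-branching": _run_evolved_branching,
    "potential-distribution": _run_potential_distribution,
    "level-power": _run_level_power,
}


def run_experiment(
    name: str,
    seed: int = 0,
    scale: float = 1.0,
    outdir: str | Path = "results",
    make_figures: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run one named experiment; returns (and writes) its data tables."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("running experiment %s (seed=%d, scale=%g) -> %s", name, seed, scale, outdir)
    return EXPERIMENTS[name](seed, scale, outdir, make_figures)
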