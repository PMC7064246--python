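"""Effective resistance, σ identities, and figure-level metric operations."""

import numpy as np
import pytest

from radeflow.core import DemandSpec, Link, Network, Node, NodeRole
from radeflow.generators import (
    GeneratorParams,
    apply_strength_rule,
    calibrate_resource_potential,
    fully_branched,
    radial_burst,
    random_network,
)
from radeflow.metrics import (
    effective_resistance,
    gini,
    inequality_stats,
    level_power_series,
    normalise_density,
    potential_distribution,
    sigma_re,
    sigma_slope,
    trajectory_metrics,
)
from radeflow.solver import direct_solve, find_max_power, sweep


@pytest.fixture(scope="module")
def chain():
    nodes = [
        Node(0, NodeRole.RESOURCE, [0.0, 0.0], potential=100.0),
        Node(1, NodeRole.CONSUMER, [1.0, 0.0]),
        Node(2, NodeRole.CONSUMER, [2.0, 0.0]),
    ]
    return Network(nodes, [Link(0, 1, 1.0), Link(1, 2, 1.0)])


class TestEffectiveResistance:
    def test_direct_link_reduces_to_link_resistance(self):
        nodes = [
            Node(0, NodeRole.RESOURCE, [0.0, 0.0], potential=100.0),
            Node(1, NodeRole.CONSUMER, [1.0, 0.0]),
        ]
        net = Network(nodes, [Link(0, 1, 4.0, 2.0)])  # R = 2
        rec = direct_solve(net, 5.0)
        assert effective_resistance(rec) == pytest.approx([2.0])

    def test_chain_oracle_values(self, chain):
        rec = direct_solve(chain, 10.0)
        assert effective_resistance(rec) == pytest.approx([2.0, 3.0])
        assert sigma_re(rec) == pytest.approx(0.5)

    def test_radial_burst_sigma_re_zero(self):
        rec = direct_solve(radial_burst(12, 1.0, resource_potential=100.0), 3.0)
        assert sigma_re(rec) == 0.0

    def test_undefined_at_zero_demand(self, chain):
        rec = direct_solve(chain, 0.0)
        with pytest.raises(ValueError):
            effective_resistance(rec)

    def test_flow_invariant_on_fixed_strength_networks(self):
        net = random_network(GeneratorParams(n_consumers=15, seed=4))
        re_values = [effective_resistance(direct_solve(net, i)) for i in (1.0, 10.0, 123.4)]
        for other in re_values[1:]:
            assert np.allclose(re_values[0], other, rtol=1e-9)


class TestInequalityStats:
    def test_sigma_identities_on_chain_oracle(self, chain):
        # sigma_RE = 0.5, so at I = 10: sigma_VC = 5 and sigma_PC = 50
        stats = inequality_stats(direct_solve(chain, 10.0))
        assert stats.sigma_vc == pytest.approx(5.0)
        assert stats.sigma_pc == pytest.approx(50.0)

    def test_radial_burst_zero_spread(self):
        net = radial_burst(8, 1.0, resource_potential=100.0)
        for demand in (1.0, 40.0):
            stats = inequality_stats(direct_solve(net, demand))
            assert stats.sigma_vc == 0.0 and stats.sigma_pc == 0.0

    def test_single_consumer_degenerate(self):
        net = radial_burst(1, 1.0, resource_potential=100.0)
        stats = inequality_stats(direct_solve(net, 5.0))
        assert stats.sigma_vc == 0.0 and stats.sigma_pc == 0.0

    def test_sigma_identities_along_a_whole_sweep(self):
        net = random_network(GeneratorParams(n_consumers=20, seed=17))
        traj = sweep(net, DemandSpec(stop=150.0))
        s_re = sigma_re(traj[0])
        for rec in traj.records[:: len(traj) // 7]:
            stats = inequality_stats(rec)
            assert stats.sigma_vc == pytest.approx(s_re * rec.demand, rel=1e-6)
            assert stats.sigma_pc == pytest.approx(s_re * rec.demand**2, rel=1e-6)

    def test_sample_convention_flag(self, chain):
        rec = direct_solve(chain, 10.0)
        pop = inequality_stats(rec).sigma_vc
        samp = inequality_stats(rec, sample=True).sigma_vc
        assert samp == pytest.approx(pop * np.sqrt(2.0))  # n=2: ddof rescaling


class TestSigmaSlope:
    def test_chain_slope_equals_sigma_re(self, chain):
        traj = sweep(chain, DemandSpec(stop=40.0))
        assert sigma_slope(traj) == pytest.approx(0.5, rel=1e-9)

    def test_radial_burst_slope_zero(self):
        # zero up to the round-off of averaging identical floats
        traj = sweep(radial_burst(6, 1.0, resource_potential=100.0), DemandSpec(stop=40.0))
        assert sigma_slope(traj) == pytest.approx(0.0, abs=1e-12)

    def test_slope_identity_on_random_network(self):
        traj = sweep(random_network(GeneratorParams(n_consumers=25, seed=8)))
        assert sigma_slope(traj) / sigma_re(traj[0]) == pytest.approx(1.0, rel=1e-6)

    def test_needs_two_records(self, chain):
        traj = sweep(chain, DemandSpec(start=1.0, step=1.0, stop=1.0))
        with pytest.raises(ValueError):
            sigma_slope(traj)


class TestNormaliseDensity:
    def test_reference_ratio_sample_is_standardised(self):
        net = random_network(GeneratorParams(n_consumers=25, seed=5))
        samples = normalise_density(sweep(net))
        ref = samples[0.75]
        assert ref.mean() == pytest.approx(0.0, abs=1e-12)
        assert ref.std() == pytest.approx(1.0, rel=1e-6)

    def test_radial_burst_normalises_to_zero(self):
        samples = normalise_density(sweep(radial_burst(8, 1.0, resource_potential=100.0)))
        for values in samples.values():
            assert np.all(values == 0.0)

    def test_spread_grows_as_ratio_falls(self):
        net = random_network(GeneratorParams(n_consumers=25, seed=5))
        samples = normalise_density(sweep(net))
        spreads = [samples[r].std() for r in (0.75, 0.5, 0.25)]
        assert spreads[0] <= spreads[1] <= spreads[2]

    def test_out_of_range_ratio_rejected(self):
        net = random_network(GeneratorParams(n_consumers=10, seed=6))
        with pytest.raises(ValueError):
            normalise_density(sweep(net), ratios=(1.5,))


@pytest.fixture(scope="module")
def branched_trajectory():
    net = fully_branched(levels=5, resource_potential=1.0)
    apply_strength_rule(net, 2.0)
    calibrate_resource_potential(net)
    return sweep(net), net


class TestLevelPowerSeries:
    def test_requires_level_labels(self):
        net = random_network(GeneratorParams(n_consumers=6, seed=1))
        with pytest.raises(ValueError):
            level_power_series(sweep(net), net)

    def test_normalised_values_bounded(self, branched_trajectory):
        traj, net = branched_trajectory
        df = level_power_series(traj, net)
        assert df["relative_power"].max() <= 1.0 + 1e-12
        assert df["relative_demand"].max() == pytest.approx(1.0)

    def test_deeper_levels_have_higher_effective_resistance(self, branched_trajectory):
        # equivalent form of "deeper levels peak at strictly lower demand"
        traj, net = branched_trajectory
        rec = traj[0]
        re = effective_resistance(rec)
        levels = np.array([n.level for n in net.consumers])
        by_level = [re[levels == l].mean() for l in range(5)]
        assert all(b > a for a, b in zip(by_level, by_level[1:]))

    def test_level0_power_rising_at_network_peak(self, branched_trajectory):
        traj, net = branched_trajectory
        df = level_power_series(traj, net)
        lvl0 = df[df["level"] == 0].reset_index(drop=True)
        peak_idx = lvl0.index[lvl0["at_network_peak"]][0]
        window = lvl0["mean_power"].iloc[max(0, peak_idx - 1): peak_idx + 2]
        assert window.is_monotonic_increasing


class TestPotentialDistribution:
    def test_branched_distinct_values_equal_levels(self, branched_trajectory):
        traj, net = branched_trajectory
        rec = find_max_power(traj)
        dist = potential_distribution(rec)
        assert len(dist) == 5
        assert dist.sum() == net.n_consumers

    def test_radial_burst_single_value(self):
        rec = direct_solve(radial_burst(9, 1.0, resource_potential=100.0), 2.0)
        dist = potential_distribution(rec)
        assert len(dist) == 1 and dist.iloc[0] == 9


class TestGiniVsSigma:
    def test_uniform_inflation_moves_sigma_not_gini(self):
        # a 50% across-the-board rise leaves relative inequality (Gini) fixed
        # while the absolute spread grows 50% — the reason sigma is preferred
        rng = np.random.default_rng(3)
        power = rng.uniform(10, 100, 50)
        inflated = 1.5 * power
        assert gini(inflated) == pytest.approx(gini(power), rel=1e-9)
        assert np.std(inflated) == pytest.approx(1.5 * np.std(power), rel=1e-12)


def test_trajectory_metrics_frame_shape(chain):
    traj = sweep(chain, DemandSpec(stop=5.0))
    df = trajectory_metrics(traj)
    assert list(df.columns) == [
        "demand", "sigma_vc", "sigma_pc", "sigma_re", "mean_ratio", "total_power",
    ]
    assert len(df) == len(traj)
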