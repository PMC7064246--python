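"""Load-flow solver: oracles, conservation laws, sweep and peak detection."""

import numpy as np
import pytest

from radeflow.core import DemandSpec, Link, Network, Node, NodeRole
from radeflow.generators import GeneratorParams, radial_burst, random_network
from radeflow.solver import (
    SingularSystemError,
    SolverConfig,
    assemble_conductance,
    direct_solve,
    find_max_power,
    solve_fixed_demand,
    sweep,
    Trajectory,
)
from conftest import make_random_network


class TestAssembleConductance:
    def test_single_link(self, single_link_network):
        net = Network(
            single_link_network.nodes, [Link(0, 1, 2.0)], single_link_network.topology
        )
        a = assemble_conductance(net).toarray()
        assert a.shape == (1, 1) and a[0, 0] == pytest.approx(0.5)

    def test_chain_hand_assembly(self, chain_network):
        a = assemble_conductance(chain_network).toarray()
        assert np.allclose(a, [[2.0, -1.0], [-1.0, 1.0]])

    def test_symmetry_on_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = assemble_conductance(make_random_network(rng)).toarray()
            assert np.allclose(a, a.T)


class TestFixedDemandSolve:
    def test_radial_burst_equal_drop(self):
        net = radial_burst(8, radius=1.0, resource_potential=100.0)
        rec = solve_fixed_demand(net, 10.0)
        assert np.allclose(rec.consumer_potentials, 90.0)
        assert np.allclose(rec.consumer_power, 900.0)

    def test_chain_hand_oracle(self, chain_network):
        for solver in (solve_fixed_demand, direct_solve):
            rec = solver(chain_network, 10.0)
            assert rec.potential_of(1) == pytest.approx(80.0, abs=1e-9)
            assert rec.potential_of(2) == pytest.approx(70.0, abs=1e-9)
        # first link carries both consumers' demand
        rec = direct_solve(chain_network, 10.0)
        assert sorted(np.abs(rec.link_flows)) == pytest.approx([10.0, 20.0])

    def test_resource_potentials_unchanged(self, chain_network):
        rec = solve_fixed_demand(chain_network, 3.0)
        assert rec.potential_of(0) == 100.0

    def test_zero_demand_flattens_potentials(self, chain_network):
        rec = direct_solve(chain_network, 0.0)
        assert np.allclose(rec.potentials, 100.0)

    def test_disconnected_system_raises(self):
        nodes = [
            Node(0, NodeRole.RESOURCE, [0.0, 0.0], potential=10.0),
            Node(1, NodeRole.CONSUMER, [1.0, 0.0]),
            Node(2, NodeRole.CONSUMER, [2.0, 0.0]),
        ]
        net = Network(nodes, [Link(0, 1, 1.0)])
        with pytest.raises(SingularSystemError):
            direct_solve(net, 1.0)

    def test_demand_must_be_positive(self, chain_network):
        with pytest.raises(ValueError):
            solve_fixed_demand(chain_network, 0.0)


class TestSolverEquivalenceAndConservation:
    """Iterative scheme vs direct oracle, Kirchhoff, and energy balance."""

    N_NETWORKS = 100

    @pytest.fixture(scope="class")
    @staticmethod
    def solved_pairs():
        rng = np.random.default_rng(2024)
        out = []
        for _ in range(TestSolverEquivalenceAndConservation.N_NETWORKS):
            net = make_random_network(rng)
            i_c = float(rng.uniform(0.5, 20.0))
            out.append((net, direct_solve(net, i_c), solve_fixed_demand(net, i_c)))
        return out

    def test_iterative_matches_direct_oracle(self, solved_pairs):
        for _, direct, iterative in solved_pairs:
            scale = max(1.0, np.max(np.abs(direct.potentials)))
            assert np.max(np.abs(direct.potentials - iterative.potentials)) <= 1e-6 * scale

    def test_kirchhoff_at_every_node(self, solved_pairs):
        for net, direct, _ in solved_pairs:
            index = {n.id: i for i, n in enumerate(net.nodes)}
            net_in = np.zeros(len(net.nodes))
            for k, link in enumerate(net.links):
                f = direct.link_flows[k]
                net_in[index[link.node_a]] -= f
                net_in[index[link.node_b]] += f
            for n in net.nodes:
                if n.role is NodeRole.CONSUMER:
                    assert net_in[index[n.id]] == pytest.approx(direct.demand, abs=1e-6)
                elif n.role is NodeRole.BRANCH_POINT:
                    assert abs(net_in[index[n.id]]) < 1e-9 * max(
                        1.0, np.max(np.abs(direct.link_flows))
                    )

    def test_energy_balance(self, solved_pairs):
        # resource output = consumer power + transport losses
        for _, direct, _ in solved_pairs:
            produced = direct.resource_output.sum()
            consumed = direct.total_power + direct.link_losses.sum()
            assert produced == pytest.approx(consumed, rel=1e-6)


class TestSweep:
    def test_single_link_peak_is_analytic(self, single_link_network):
        # P(I) = I (100 - I): peak at I = V_R / (2R) = 50 with P = 2500, V_C = 50
        traj = sweep(single_link_network)
        peak = find_max_power(traj)
        assert peak.demand == pytest.approx(50.0)
        assert peak.total_power == pytest.approx(2500.0)
        assert peak.consumer_potentials[0] == pytest.approx(50.0)
        assert peak.mean_potential_ratio == pytest.approx(0.5)

    def test_negative_power_terminates_past_v_c_zero(self, single_link_network):
        traj = sweep(single_link_network)
        assert traj.termination == Trajectory.NEGATIVE_POWER
        assert traj[-1].total_power < 0
        assert traj[-1].demand == pytest.approx(100.1)
        assert all(r.total_power >= 0 for r in traj.records[:-1])

    def test_demand_grid_is_regular(self, single_link_network):
        traj = sweep(single_link_network, DemandSpec(start=1.0, step=0.5, stop=30.0))
        assert traj.termination == Trajectory.DEMAND_CEILING
        assert np.allclose(np.diff(traj.demands), 0.5)

    def test_radial_burst_superposes_single_links(self, single_link_network):
        burst = radial_burst(8, radius=1.0, resource_potential=100.0)
        t1 = sweep(single_link_network, DemandSpec(stop=90.0))
        t8 = sweep(burst, DemandSpec(stop=90.0))
        assert np.allclose(t8.total_power, 8.0 * t1.total_power)

    def test_sweep_records_match_both_solvers(self):
        net = random_network(GeneratorParams(n_consumers=10, seed=9))
        traj = sweep(net, DemandSpec(start=1.0, step=1.0, stop=60.0))
        for k in (0, 10, 40):
            rec = traj[k]
            ref = direct_solve(net, rec.demand)
            assert np.allclose(rec.potentials, ref.potentials, rtol=1e-9)
            it = solve_fixed_demand(net, rec.demand)
            assert np.allclose(rec.potentials, it.potentials, atol=1e-6 * np.abs(ref.potentials).max())

    def test_potentials_affine_in_demand(self):
        # fit V(I) on two sweep points, predict a third to 1e-9
        net = random_network(GeneratorParams(n_consumers=15, seed=13))
        r1, r2, r3 = (direct_solve(net, i) for i in (2.0, 50.0, 80.0))
        slope = (r2.potentials - r1.potentials) / (50.0 - 2.0)
        predicted = r1.potentials + slope * (80.0 - 2.0)
        assert np.allclose(predicted, r3.potentials, rtol=1e-9, atol=1e-9)

    def test_total_power_concave_along_sweep(self):
        net = random_network(GeneratorParams(n_consumers=12, seed=21))
        traj = sweep(net)
        second_diff = np.diff(traj.total_power, n=2)
        assert np.all(second_diff <= 1e-6 * np.abs(traj.total_power).max())

    def test_total_link_length_invariant_under_sweep(self):
        net = random_network(GeneratorParams(n_consumers=10, seed=2))
        before = net.total_link_length()
        sweep(net)
        assert net.total_link_length() == before


class TestFindMaxPower:
    def test_monotone_decreasing_trajectory_returns_first(self, single_link_network):
        # start the grid past the peak: power only falls, argmax is the first record
        traj = sweep(single_link_network, DemandSpec(start=60.0, step=1.0, stop=90.0))
        assert find_max_power(traj).demand == pytest.approx(60.0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory([], Trajectory.DEMAND_CEILING)
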