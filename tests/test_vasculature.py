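"""Vessel networks: synthesis statistics, Poiseuille flow, collapse,
and 1D nanoparticle transport on the graph."""

import numpy as np
import pytest

from nanotherm import (collapse_vessels, generate_network, junction_imbalance,
                       make_grid, solve_network_flow, spherical_tumour_state,
                       step_np_vessel_1d)
from nanotherm.vasculature import (VesselNetwork, _murray_radii,
                                   build_vessel_mesh, calibrated_network,
                                   replace_network, VesselTransport1D)


def single_pipe(R=1e-2, L=1.0, dp=100.0, omega=0.0):
    net = VesselNetwork(
        nodes=[[0.0, 0.5], [L, 0.5]], segments=[[0, 1]], radii=[R],
        inlet_nodes=[0], outlet_nodes=[1],
        inlet_pressure=dp, outlet_pressure=0.0,
    )
    net.omega[:] = omega
    return net


class TestPoiseuilleFlow:
    def test_single_pipe_reference_flow(self):
        """Q = pi R^4 dp / (8 mu L) for R=10 um, dp=100 Pa, mu=3.5 mPa s."""
        net = solve_network_flow(single_pipe(), mu_blood=3.5e-3)
        expected = np.pi * 1e-8 * 100.0 / (8 * 3.5e-3 * 1.0)
        assert net.flows[0] == pytest.approx(expected, rel=1e-12)
        assert net.flows[0] == pytest.approx(1.122e-4, rel=1e-3)

    def test_zero_pressure_drop_zero_flow(self):
        net = solve_network_flow(single_pipe(dp=0.0))
        assert net.flows[0] == 0.0

    def test_symmetric_bifurcation_splits_evenly(self):
        net = VesselNetwork(
            nodes=[[0, 1], [1, 1], [2, 1.5], [2, 0.5]],
            segments=[[0, 1], [1, 2], [1, 3]],
            radii=[1e-2, 8e-3, 8e-3],
            inlet_nodes=[0], outlet_nodes=[2, 3],
        )
        net = solve_network_flow(net)
        assert net.flows[1] == pytest.approx(net.flows[2], rel=1e-14)
        assert net.flows[0] == pytest.approx(net.flows[1] + net.flows[2],
                                             rel=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_junction_conservation_any_network(self, seed):
        net = generate_network((0, 0, 2.0, 2.0), n_terminal=40, seed=seed)
        net = solve_network_flow(net)
        assert junction_imbalance(net) <= 1e-12 * np.abs(net.flows).max()


class TestGeneration:
    def test_radius_statistics(self):
        net = generate_network((0, 0, 2.7, 3.5), target_mean_radius=6.98e-3,
                               radius_range=(1.6e-3, 30e-3), n_terminal=150,
                               seed=0)
        assert 6.28e-3 <= net.mean_radius(False) <= 7.68e-3
        assert net.radii.min() >= 1.6e-3
        assert net.radii.max() <= 30e-3

    def test_single_inlet_connected_tree(self):
        net = generate_network((0, 0, 2.0, 2.0), n_terminal=30, seed=3)
        assert len(net.inlet_nodes) == 1
        # a tree over n nodes has n-1 segments and no cycles
        assert net.n_segments == net.n_nodes - 1

    def test_murray_law_exact_at_unclipped_bifurcations(self):
        net = generate_network((0, 0, 2.0, 2.0), n_terminal=60, seed=1)
        children = {}
        for k, (a, b) in enumerate(net.segments):
            children.setdefault(a, []).append(k)
        parent_of = {b: k for k, (a, b) in enumerate(net.segments)}
        rmin, rmax = 1.6e-3, 30e-3
        checked = 0
        for node, kids in children.items():
            if node not in parent_of or len(kids) < 2:
                continue
            rp = net.radii[parent_of[node]]
            if rp >= rmax or any(net.radii[k] <= rmin for k in kids):
                continue  # clipping breaks the law by construction
            assert rp ** 3 == pytest.approx(
                sum(net.radii[k] ** 3 for k in kids), rel=1e-9)
            checked += 1
        assert checked > 5

    def test_equal_children_closed_form(self):
        """Murray with exponent 3 and equal children: r_p = 2^(1/3) r_c."""
        segs = [(0, 1), (1, 2), (1, 3)]
        radii = _murray_radii(4, segs, 5e-3, 3.0)
        assert radii[0] == pytest.approx(2 ** (1 / 3) * 5e-3, rel=1e-12)

    def test_deterministic_given_seed(self):
        a = generate_network((0, 0, 2.0, 2.0), n_terminal=50, seed=9)
        b = generate_network((0, 0, 2.0, 2.0), n_terminal=50, seed=9)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_array_equal(a.segments, b.segments)
        np.testing.assert_array_equal(a.radii, b.radii)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_network((0, 0, 1, 1), target_mean_radius=40e-3)
        with pytest.raises(ValueError):
            generate_network((0, 0, 1, 1), n_terminal=1)

    def test_length_density_calibration(self):
        net = calibrated_network((0, 0, 2.7, 3.5), 12.0, seed=1)
        density = net.total_length(False) / (2.7 * 3.5)
        assert density == pytest.approx(12.0, rel=0.10)

    def test_json_round_trip(self, tmp_path):
        net = generate_network((0, 0, 1.5, 1.5), n_terminal=20, seed=2)
        net.to_json(tmp_path / "net.json")
        back = VesselNetwork.from_json(tmp_path / "net.json")
        np.testing.assert_allclose(back.nodes, net.nodes)
        np.testing.assert_array_equal(back.segments, net.segments)
        np.testing.assert_allclose(back.radii, net.radii)


@pytest.fixture(scope="module")
def grid_and_net():
    g = make_grid(60, 60, 2.0, 2.0)
    net = generate_network((0, 0, 2.0, 2.0), n_terminal=80, seed=4)
    return g, net


class TestCollapse:

    def test_no_tumour_no_collapse(self, grid_and_net):
        g, net = grid_and_net
        st = spherical_tumour_state(g, 0.0, (1.0, 1.0))
        assert not collapse_vessels(net, st, 0.5).collapsed.any()

    def test_full_tumour_full_collapse(self, grid_and_net):
        g, net = grid_and_net
        st = spherical_tumour_state(g, 0.0, (1.0, 1.0),
                                    tumour_sat={"St": 1.0})
        st.St[:] = 1.0
        c = collapse_vessels(net, st, 0.5)
        assert c.collapsed.all()
        c = solve_network_flow(c) if c.active().any() else c
        assert c.flows is None or np.all(c.flows[c.active()] == 0)

    def test_collapse_localised_to_tumour(self, grid_and_net):
        g, net = grid_and_net
        st = spherical_tumour_state(g, 0.4, (1.0, 1.0))
        c = collapse_vessels(net, st, 0.5)
        mids = c.midpoints
        r = np.hypot(mids[:, 0] - 1.0, mids[:, 1] - 1.0)
        # segments collapsed by the St rule itself lie inside ~0.45 mm
        from nanotherm.vasculature import _sample_nodal

        st_mid = _sample_nodal(g, st.St, mids)
        rule_collapsed = st_mid > 0.5
        assert np.all(r[rule_collapsed] <= 0.45)
        # everything else flagged is disconnected from the inlet, and
        # every surviving segment is reachable (has nonzero flow)
        c = solve_network_flow(c)
        assert np.all(np.abs(c.flows[c.active()]) > 0)


class TestTransport1D:
    def test_zero_inlet_stays_zero(self):
        net = solve_network_flow(single_pipe())
        net = step_np_vessel_1d(net, 60.0, 0.0, 1.3e-5, h_1d=0.05)
        assert np.all(net.omega == 0.0)

    def test_steady_diffusion_fills_pipe(self):
        """Both ends held at 2e-3, no flow: interior converges there."""
        net = single_pipe(dp=0.0)
        net = replace_network(net, inlet_nodes=np.array([0, 1]))
        net = solve_network_flow(net)
        for _ in range(400):
            net = step_np_vessel_1d(net, 50.0, 2e-3, 1.3e-3, h_1d=0.1)
        assert np.all(np.abs(net.omega - 2e-3) < 2e-5)

    def test_plug_flow_reaches_outlet(self):
        """Constant inlet, >= 5 transit times: outlet within 1%."""
        net = solve_network_flow(single_pipe(R=5e-3, L=1.0, dp=50.0))
        Q = net.flows[0]
        v = Q / (np.pi * 25e-6)  # mm/s
        transit = 1.0 / v
        dt = transit / 50
        mesh = build_vessel_mesh(net, 0.02)
        tr = VesselTransport1D(mesh, dt, 1.3e-5)
        om = np.zeros(len(mesh.points))
        for _ in range(5 * 50):
            om, _ = tr.step(om, 2e-3)
        out = mesh.node_of_net_node[1]
        assert om[out] == pytest.approx(2e-3, rel=0.01)

    def test_bounded_by_inlet_concentration(self):
        net = solve_network_flow(single_pipe())
        mesh = build_vessel_mesh(net, 0.02)
        tr = VesselTransport1D(mesh, 60.0, 1.3e-5)
        om = np.zeros(len(mesh.points))
        for _ in range(100):
            om, _ = tr.step(om, 2e-3)
        assert om.min() >= -1e-15
        assert om.max() <= 2e-3 * (1 + 1e-9)

    def test_mass_ledger_closes(self):
        """d(mass)/dt = inlet - outlet - exchange to 1e-8 relative."""
        net = generate_network((0, 0, 1.5, 1.5), n_terminal=25, seed=5)
        net = solve_network_flow(net)
        mesh = build_vessel_mesh(net, 0.05)
        tr = VesselTransport1D(mesh, 30.0, 1.3e-5)
        rng = np.random.default_rng(0)
        sink = rng.uniform(0, 1e-12, len(mesh.elems))
        om = np.zeros(len(mesh.points))
        for _ in range(20):
            om, led = tr.step(om, 2e-3, sink)
            rhs = led["inlet_in"] - led["outlet_out"] - led["exchange"]
            scale = max(abs(led["inlet_in"]), abs(led["d_mass_free"]), 1e-300)
            assert abs(led["d_mass_free"] - rhs) <= 1e-8 * scale

    def test_invalid_dt(self):
        net = solve_network_flow(single_pipe())
        with pytest.raises(ValueError):
            step_np_vessel_1d(net, -1.0, 0.0, 1e-5)
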