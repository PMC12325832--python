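"""Interstitial nanoparticle transport: Darcy advection, transvascular
exchange, lymphatic drainage, and the backward-Euler balance."""

import numpy as np
import pytest

from conftest import uniform_state
from nanotherm import darcy_velocity, make_grid, spherical_tumour_state
from nanotherm.transport import (NPTransportStepper, SimState, TransportParams,
                                 drainage_coefficient, lymphatic_drainage,
                                 transvascular_exchange_discrete,
                                 transvascular_exchange_homogenised)


class TestDarcyVelocity:
    def test_uniform_pressure_zero_velocity(self):
        g = make_grid(8, 8, 1.0, 1.0)
        st = uniform_state(g, pl=250.0)
        v = darcy_velocity(st, TransportParams())
        np.testing.assert_allclose(v, 0.0, atol=1e-18)

    def test_linear_pressure_analytic_gradient(self):
        g = make_grid(10, 6, 1.0, 0.6)
        st = uniform_state(g)
        st.pl = 100.0 * g.nodes[:, 0]
        p = TransportParams(k_over_mu=1e-6)
        v = darcy_velocity(st, p)
        np.testing.assert_allclose(v[:, 0], -1e-4, rtol=1e-12)
        np.testing.assert_allclose(v[:, 1], 0.0, atol=1e-18)

    def test_outward_flow_from_tumour(self, quarter_grid, quarter_state):
        """Elevated tumour IFP drives interstitial fluid outward."""
        g = quarter_grid
        v = darcy_velocity(quarter_state, TransportParams())
        rvec = g.nodes - np.array([0.0, 0.5])
        r = np.hypot(rvec[:, 0], rvec[:, 1])
        host = (r > 0.1) & (r < 0.75)
        dots = np.einsum("ij,ij->i", v[host], rvec[host])
        assert np.all(dots >= -1e-18)


class TestExchangeHomogenised:
    def setup_method(self):
        self.g = make_grid(2, 2, 1.0, 1.0)

    def sim(self, omega_v, omega_l):
        s = SimState(grid=self.g)
        s.omega_v[:] = omega_v
        s.omega_l[:] = omega_l
        return s

    def test_zero_concentrations_zero_transfer(self):
        st = uniform_state(self.g, pl=0.0, pv=400.0)
        m = transvascular_exchange_homogenised(st, self.sim(0, 0),
                                               TransportParams())
        np.testing.assert_allclose(m, 0.0)

    def test_interendothelial_reference_value_mean_drag(self):
        """rho_v eps_v Lp (S/V) dp (omega_v+omega_l)/2 at the worked point."""
        st = uniform_state(self.g, pl=0.0, eps_v=0.028, pv=400.0)
        p = TransportParams(SoverV=20.0, drag_concentration="mean", P_v=0.0)
        m = transvascular_exchange_homogenised(st, self.sim(2e-3, 0.0), p)
        np.testing.assert_allclose(m, 2.24e-11, rtol=1e-6)

    def test_interendothelial_upwind_carries_vessel_concentration(self):
        st = uniform_state(self.g, pl=0.0, eps_v=0.028, pv=400.0)
        p = TransportParams(SoverV=20.0, drag_concentration="upwind", P_v=0.0)
        m = transvascular_exchange_homogenised(st, self.sim(2e-3, 0.0), p)
        np.testing.assert_allclose(m, 4.48e-11, rtol=1e-6)
        # empty vasculature drives no influx in upwind mode
        m0 = transvascular_exchange_homogenised(st, self.sim(0.0, 2e-3), p)
        np.testing.assert_allclose(m0, 0.0, atol=1e-30)

    def test_transendothelial_value_and_clamp(self):
        st = uniform_state(self.g, pl=0.0, eps_v=0.028, pv=0.0)
        p = TransportParams(SoverV=20.0, Lp_v=0.0)
        m = transvascular_exchange_homogenised(st, self.sim(2e-3, 0.0), p)
        np.testing.assert_allclose(m, 2.24e-12, rtol=1e-6)
        m_rev = transvascular_exchange_homogenised(st, self.sim(2e-3, 3e-3), p)
        np.testing.assert_allclose(m_rev, 0.0, atol=1e-30)


class TestExchangeDiscrete:
    def test_transendothelial_line_density(self):
        """2 pi R P_v rho_v domega at the mean capillary radius."""
        m = transvascular_exchange_discrete(
            radii=np.array([6.98e-3]), pv_hat=np.array([0.0]),
            omega_v_hat=np.array([2e-3]), pl_line=np.array([0.0]),
            omega_l_line=np.array([0.0]), params=TransportParams(Lp_v=0.0))
        np.testing.assert_allclose(m, 1.754e-13, rtol=1e-3)

    def test_zero_when_balanced(self):
        p = TransportParams()
        m = transvascular_exchange_discrete(
            np.array([7e-3]), np.array([100.0]), np.array([1e-3]),
            np.array([100.0]), np.array([1e-3]), p)
        np.testing.assert_allclose(m, 0.0, atol=1e-30)

    def test_linear_in_circumference(self):
        p = TransportParams()
        args = dict(pv_hat=np.array([500.0]), omega_v_hat=np.array([2e-3]),
                    pl_line=np.array([0.0]), omega_l_line=np.array([0.0]),
                    params=p)
        m1 = transvascular_exchange_discrete(np.array([5e-3]), **args)
        m2 = transvascular_exchange_discrete(np.array([10e-3]), **args)
        assert m2[0] == pytest.approx(2 * m1[0], rel=1e-12)

    def test_collapsed_contributes_exactly_zero(self):
        p = TransportParams()
        m = transvascular_exchange_discrete(
            np.array([7e-3, 7e-3]), np.array([500.0, 500.0]),
            np.array([2e-3, 2e-3]), np.zeros(2), np.zeros(2), p,
            collapsed=np.array([False, True]))
        assert m[1] == 0.0
        assert m[0] > 0.0


class TestLymphaticDrainage:
    def setup_method(self):
        self.g = make_grid(2, 2, 1.0, 1.0)

    def test_reference_value(self):
        st = uniform_state(self.g, pl=400.0, pt=0.0)
        sim = SimState(grid=self.g)
        sim.omega_l[:] = 2e-3
        p = TransportParams(p_coll_ly=1e9)  # impairment factor ~ 1
        m = lymphatic_drainage(st, sim, p)
        np.testing.assert_allclose(m, 8.32e-10, rtol=1e-4)

    def test_zero_omega_zero_drainage(self):
        st = uniform_state(self.g, pl=400.0)
        m = lymphatic_drainage(st, SimState(grid=self.g), TransportParams())
        np.testing.assert_allclose(m, 0.0)

    def test_impaired_at_collapse_pressure(self):
        p = TransportParams()
        st = uniform_state(self.g, pl=400.0, pt=p.p_coll_ly)
        sim = SimState(grid=self.g)
        sim.omega_l[:] = 2e-3
        np.testing.assert_allclose(lymphatic_drainage(st, sim, p), 0.0)

    def test_always_a_sink(self):
        st = uniform_state(self.g, pl=-100.0, pt=0.0)
        assert np.all(drainage_coefficient(st, TransportParams()) >= 0)

    def test_zero_collapse_pressure_rejected(self):
        with pytest.raises(ValueError):
            TransportParams(p_coll_ly=0.0)


def be_0d_oracle(params, st_vals, omega_v, dt, n_steps):
    """Independent backward-Euler integration of the 0D nanoparticle
    balance: s domega/dt = M_inter + M_trans - M_drain, solving the
    piecewise-linear implicit equation per step by fixed-point iteration
    run to machine tolerance."""
    eps, Sl, eps_v, pl, pt, pv = st_vals
    s = eps * Sl * params.rho_l
    dp = pv - pl
    Ki = params.rho_v * eps_v * params.SoverV * params.Lp_v * dp
    Kt = params.rho_v * eps_v * params.SoverV * params.P_v
    impair = max(1 - pt / params.p_coll_ly, 0.0)
    kd = params.rho_l * params.LpSoverV_ly * max(pl - params.p_ly, 0) * impair
    x = 0.0
    for _ in range(n_steps):
        xn = x
        for _ in range(300):
            if params.drag_concentration == "mean":
                inter = Ki * 0.5 * (omega_v + xn)
            else:
                inter = Ki * (omega_v if dp >= 0 else xn)
            trans = Kt * max(omega_v - xn, 0.0)
            xn_next = x + dt / s * (inter + trans - kd * xn)
            if abs(xn_next - xn) < 1e-20:
                xn = xn_next
                break
            xn = xn_next
        x = xn
    return x


class TestTransportStepper:
    @pytest.mark.parametrize("drag", ["upwind", "mean"])
    def test_matches_0d_backward_euler_oracle(self, drag):
        """Uniform fields, homogenised exchange only: nodal omega matches
        the scalar ODE integrated independently, to 1e-10 relative."""
        g = make_grid(4, 4, 1.0, 1.0)
        st = uniform_state(g, pl=200.0, eps_v=0.028)
        p = TransportParams(drag_concentration=drag)
        stp = NPTransportStepper(g, st, p, dt=60.0)
        om = np.zeros(g.n_nodes)
        for _ in range(20):
            guess = om
            for _ in range(60):
                new = stp.step(om, 2e-3, omega_l_guess=guess)
                if np.max(np.abs(new - guess)) < 1e-18:
                    break
                guess = new
            om = new
        oracle = be_0d_oracle(p, (0.8, 0.4, 0.028, 200.0, 200.0, 600.0),
                              2e-3, 60.0, 20)
        np.testing.assert_allclose(om, oracle, rtol=1e-10)

    def test_no_sources_stays_zero(self):
        g = make_grid(6, 6, 1.0, 1.0)
        st = uniform_state(g, pl=0.0, eps_v=0.0)
        stp = NPTransportStepper(g, st, TransportParams(), dt=60.0)
        om = np.zeros(g.n_nodes)
        for _ in range(5):
            om = stp.step(om, 0.0)
        np.testing.assert_allclose(om, 0.0)

    def test_closed_domain_conserves_mass(self):
        """No flux, no drainage, no exchange: a blob keeps its mass."""
        g = make_grid(20, 20, 1.0, 1.0)
        st = uniform_state(g, pl=0.0, eps_v=0.0)
        stp = NPTransportStepper(g, st, TransportParams(), dt=60.0)
        r = np.hypot(g.nodes[:, 0] - 0.5, g.nodes[:, 1] - 0.5)
        om = np.where(r < 0.2, 1e-3, 0.0)
        m0 = stp.total_mass(om)
        for _ in range(10):
            om = stp.step(om, 0.0)
            assert stp.total_mass(om) == pytest.approx(m0, rel=1e-8)
            assert om.min() >= -1e-16

    def test_mass_ledger_closes_over_protocol(self, quarter_grid,
                                              quarter_state):
        """Tissue mass change equals exchange - drainage - advective
        outflow, accumulated over a full injection/decay cycle."""
        g, st = quarter_grid, quarter_state
        stp = NPTransportStepper(g, st, TransportParams(), dt=60.0,
                                 outflow_edges=("bottom", "right"))
        om = np.zeros(g.n_nodes)
        for k in range(60):
            om = stp.step(om, 2e-3 if k < 40 else 0.0)
        led = stp.ledger
        net = led["exchange"] - led["drainage"] - led["advection"]
        assert stp.total_mass(om) == pytest.approx(net, rel=1e-6)

    def test_maximum_principle_nonnegative(self, quarter_grid, quarter_state):
        stp = NPTransportStepper(quarter_grid, quarter_state,
                                 TransportParams(), dt=60.0,
                                 outflow_edges=("bottom", "right"))
        om = np.zeros(quarter_grid.n_nodes)
        for _ in range(20):
            om = stp.step(om, 2e-3)
            assert om.min() >= -1e-16

    def test_requires_positive_dt(self, quarter_grid, quarter_state):
        with pytest.raises(ValueError):
            NPTransportStepper(quarter_grid, quarter_state,
                               TransportParams(), dt=0.0)


class TestHomogenisedDiscreteConsistency:
    def test_dense_line_array_matches_volumetric_exchange(self):
        """A regular array of identical straight vessels whose line
        density reproduces eps_v * S/V exchanges the same total mass as
        the homogenised form, within 5%."""
        from nanotherm.fem import build_line_coupling

        g = make_grid(25, 25, 0.5, 0.5)
        R = 6.98e-3
        n_lines = 12
        xs = (np.arange(n_lines) + 0.5) * 0.5 / n_lines
        p0 = np.column_stack([xs, np.zeros(n_lines)])
        p1 = np.column_stack([xs, np.full(n_lines, 0.5)])
        coup = build_line_coupling(g, p0, p1)
        lam = coup.total_length / 0.25  # mm per mm^2

        p = TransportParams()
        # equivalent homogenised vasculature: eps_v*(S/V) = 2 pi R lambda
        eps_v_eq = 2 * np.pi * R * lam / p.SoverV
        st = uniform_state(g, pl=100.0, eps_v=eps_v_eq, pv=500.0)

        m_line = transvascular_exchange_discrete(
            np.full(len(coup.lengths), R), np.full(len(coup.lengths), 500.0),
            np.full(len(coup.lengths), 2e-3), np.full(len(coup.lengths), 100.0),
            np.zeros(len(coup.lengths)), p)
        total_discrete = float(coup.spread(m_line).sum())

        sim = SimState(grid=g)
        sim.omega_v[:] = 2e-3
        m_hom = transvascular_exchange_homogenised(st, sim, p)
        total_hom = float(np.sum(m_hom * g.nodal_volumes()))
        assert total_discrete == pytest.approx(total_hom, rel=0.05)
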