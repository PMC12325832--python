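"""Treatment protocols and the three reference experiments.

* ``run_idealised``  - quarter-domain spherical tumour, homogenised
  vasculature, lumped Pennes perfusion sink; 60-min protocol with a
  40-min nanoparticle infusion and a 20-60-min alternating-magnetic-field
  (AMF) window.
* ``run_discrete``   - 2.7 x 3.5 mm domain with a synthetic microvascular
  tree (single feeding arteriole, capillary radius statistics), vessel
  collapse in the tumour, 1D blood flow and nanoparticle transport,
  line-coupled transvascular exchange, and a choice of perfusion-cooling
  model (discrete line sink, lumped Pennes, or none).
* ``run_mouse``      - 9.5 x 9.5 mm mouse-leg domain with an 8 x 4 mm
  elliptical tumour, prescribed interstitial nanoparticle distribution
  (homogeneous or clustered, equal integrated mass), temperature-only
  solve from a 29 degC baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .bioheat import HeatStepper, ThermalParams, heat_source, vessel_line_heat_source
from .fem import EdgeSpec, SolverConfig, build_line_coupling
from .grid import Grid2D, make_grid
from .microenv import (MMHG_TO_PA, TissueState, clustered_np_field,
                       ellipse_tumour_state, spherical_tumour_state, tumour_mask)
from .transport import (NPTransportStepper, SimState, TransportParams,
                        transvascular_exchange_discrete)
from .vasculature import (VesselTransport1D, build_vessel_mesh,
                          calibrated_network, collapse_vessels,
                          solve_network_flow)

__all__ = [
    "Protocol",
    "RunResult",
    "run_idealised",
    "run_discrete",
    "run_mouse",
    "run_idealised_batch",
    "summarise",
]

CELSIUS = 273.15


@dataclass
class Protocol:
    """Treatment schedule (seconds)."""

    t_end: float = 3600.0
    injection: tuple[float, float] = (0.0, 2400.0)  # NP infusion window
    amf: tuple[float, float] = (1200.0, 3600.0)  # AMF (heating) window
    omega_v_injected: float = 2.0e-3  # vascular Dirichlet mass fraction
    dt: float = 60.0

    def __post_init__(self):
        t0, t1 = self.injection
        t2, t3 = self.amf
        if not (0 <= t0 <= t1 <= self.t_end and 0 <= t2 <= t3 <= self.t_end):
            raise ValueError("protocol windows must be ordered within [0, t_end]")

    def injecting(self, t_new: float) -> bool:
        t0, t1 = self.injection
        return (t0 < t_new <= t1) or (t0 == 0 and t_new <= t1 and t_new > 0)

    def amf_on(self, t_new: float) -> bool:
        t2, t3 = self.amf
        return t2 < t_new <= t3

    def omega_v_at(self, t_new: float) -> float:
        return self.omega_v_injected if self.injecting(t_new) else 0.0


@dataclass
class RunResult:
    """Time series, snapshots and metadata of one scenario run."""

    times: np.ndarray
    T_avg: np.ndarray
    T_max: np.ndarray
    T_min: np.ndarray
    tissue_np_mass: np.ndarray
    vessel_np_mass: np.ndarray
    snapshots: dict  # t -> {"T": ..., "omega_l": ...}
    profiles: dict  # label -> (x coords, values)
    grid: Grid2D
    config: dict
    seed: int | None = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time series must be strictly increasing")

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def peak_avg(self) -> tuple[float, float]:
        """(peak domain-average T in K, time of the peak)."""
        k = int(np.argmax(self.T_avg))
        return float(self.T_avg[k]), float(self.times[k])

    def snapshot_at(self, t: float) -> dict:
        key = min(self.snapshots, key=lambda s: abs(s - t))
        if abs(key - t) > 1e-6:
            raise KeyError(f"no snapshot at t={t} (closest: {key})")
        return self.snapshots[key]

    def spread_at(self, t: float) -> float:
        """max - min nodal temperature of the snapshot at time t (K)."""
        T = self.snapshot_at(t)["T"]
        return float(T.max() - T.min())

    def to_csv(self, path) -> None:
        from .io import write_timeseries_csv

        write_timeseries_csv(path, {
            "t_s": self.times, "T_avg_K": self.T_avg, "T_max_K": self.T_max,
            "T_min_K": self.T_min, "tissue_np_mass_g": self.tissue_np_mass,
            "vessel_np_mass_g": self.vessel_np_mass,
        })


def _series_append(series, t, T, V, m_tissue, m_vessel):
    series["times"].append(t)
    series["T_avg"].append(float(np.sum(T * V) / V.sum()))
    series["T_max"].append(float(T.max()))
    series["T_min"].append(float(T.min()))
    series["tissue_np_mass"].append(m_tissue)
    series["vessel_np_mass"].append(m_vessel)


def _finish(series, snapshots, profiles, grid, config, seed=None) -> RunResult:
    return RunResult(
        times=np.asarray(series["times"]), T_avg=np.asarray(series["T_avg"]),
        T_max=np.asarray(series["T_max"]), T_min=np.asarray(series["T_min"]),
        tissue_np_mass=np.asarray(series["tissue_np_mass"]),
        vessel_np_mass=np.asarray(series["vessel_np_mass"]),
        snapshots=snapshots, profiles=profiles, grid=grid, config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scenario 1: idealised spherical tumour, homogenised vasculature
# ---------------------------------------------------------------------------


def run_idealised(omega_inj: float = 2.0e-3, SAR: float = 2000.0, w: float = 0.0,
                  *, nx: int = 120, ny: int = 120, Lx: float = 0.5, Ly: float = 0.5,
                  r_tumour: float = 0.4, protocol: Protocol | None = None,
                  solver: SolverConfig | None = None,
                  tparams: TransportParams | None = None,
                  thermal: ThermalParams | None = None,
                  snapshot_times: tuple = (1200.0, 2400.0, 3600.0),
                  state: TissueState | None = None,
                  full_domain: bool = False) -> RunResult:
    """Quarter-domain idealised scenario (tumour centre at the upper-left
    corner; symmetry edges top and left, Robin edges bottom and right).

    With ``full_domain=True`` the tumour sits at the domain centre and all
    four edges are Robin (used by the symmetry verification).
    """
    if omega_inj < 0 or SAR < 0 or w < 0:
        raise ValueError("parameters must be non-negative")
    protocol = protocol or Protocol(omega_v_injected=omega_inj)
    solver = solver or SolverConfig(dt=protocol.dt, t_end=protocol.t_end)
    tparams = tparams or TransportParams()
    thermal = thermal or ThermalParams(SAR=SAR, w=w)

    grid = make_grid(nx, ny, Lx, Ly)
    if state is None:
        centre = (Lx / 2, Ly / 2) if full_domain else (0.0, Ly)
        state = spherical_tumour_state(grid, r_tumour, centre)

    hb = EdgeSpec("robin", h=thermal.h_tissue, value=thermal.T_b)
    if full_domain:
        boundary = {e: hb for e in ("left", "right", "bottom", "top")}
    else:
        boundary = {"bottom": hb, "right": hb,
                    "top": EdgeSpec("noflux"), "left": EdgeSpec("noflux")}

    outflow = (("left", "right", "bottom", "top") if full_domain
               else ("bottom", "right"))
    transport = NPTransportStepper(grid, state, tparams, solver.dt,
                                   mode="homogenised", linear_rtol=solver.linear_rtol,
                                   outflow_edges=outflow)
    heat = HeatStepper(grid, state, thermal, tparams, solver.dt, boundary,
                       linear_rtol=solver.linear_rtol)

    sim = SimState(grid=grid, T=np.full(grid.n_nodes, thermal.T_b))
    V = grid.nodal_volumes()
    series = {k: [] for k in ("times", "T_avg", "T_max", "T_min",
                              "tissue_np_mass", "vessel_np_mass")}
    snapshots, profiles = {}, {}
    _series_append(series, 0.0, sim.T, V, transport.total_mass(sim.omega_l), 0.0)

    t = 0.0
    for _ in range(solver.n_steps):
        t += solver.dt
        om_v = protocol.omega_v_at(t)
        # Picard sweeps for the clamped transendothelial term
        guess = sim.omega_l
        for sweep in range(solver.max_sweeps):
            new_om = transport.step(sim.omega_l, om_v, omega_l_guess=guess)
            rel = np.linalg.norm(new_om - guess) / max(np.linalg.norm(new_om), 1e-300)
            guess = new_om
            if rel < solver.fp_rtol:
                break
        sim.omega_l = guess
        sim.omega_v = np.where(state.eps_v > 0, om_v, 0.0)
        Qp = heat_source(state, sim, thermal, tparams, amf_on=protocol.amf_on(t))
        sim.T = heat.step(sim.T, Qp)
        sim.t = t
        if sim.omega_l.min() < -1e-12:
            raise RuntimeError("negative nanoparticle mass fraction")

        _series_append(series, t, sim.T, V, transport.total_mass(sim.omega_l), 0.0)
        if any(abs(t - ts) < 1e-9 for ts in snapshot_times):
            snapshots[t] = {"T": sim.T.copy(), "omega_l": sim.omega_l.copy()}

    config = {"scenario": "idealised", "omega_inj": omega_inj, "SAR": SAR, "w": w,
              "nx": nx, "ny": ny, "Lx": Lx, "Ly": Ly, "r_tumour": r_tumour,
              "protocol": asdict(protocol), "full_domain": full_domain}
    return _finish(series, snapshots, profiles, grid, config)


def run_idealised_batch(omega_values=(2.0e-3, 1.0e-3, 0.5e-3),
                        sar_values=(2000.0, 1500.0, 1000.0),
                        w_values=(0.0, 0.009, 0.018, 0.036), **kwargs) -> dict:
    """The full idealised parameter grid; keys (omega, SAR, w)."""
    out = {}
    for om in omega_values:
        for sar in sar_values:
            for w in w_values:
                out[(om, sar, w)] = run_idealised(om, sar, w, **kwargs)
    return out


# ---------------------------------------------------------------------------
# Scenario 2: discrete microvascular network
# ---------------------------------------------------------------------------


def run_discrete(beta_T: float = 2e-5, perfusion_model: str = "discrete",
                 network_seed: int = 0, *, w: float = 0.036,
                 nx: int = 108, ny: int = 140, Lx: float = 2.7, Ly: float = 3.5,
                 r_tumour: float = 0.8, centre: tuple = (1.35, 1.75),
                 omega_inj: float = 2.0e-3, SAR: float = 2000.0,
                 length_density: float = 12.0,
                 protocol: Protocol | None = None,
                 solver: SolverConfig | None = None,
                 tparams: TransportParams | None = None,
                 thermal: ThermalParams | None = None,
                 profile_y: float = 1.8,
                 transmural_offset: float = None,
                 w_host: float = 0.036,
                 network=None, state: TissueState | None = None) -> RunResult:
    """Discrete-vasculature scenario on the full 2.7 x 3.5 mm domain.

    ``perfusion_model``: 'discrete' (line sink with ``beta_T``), 'lumped'
    (Pennes sink with rate ``w``), or 'none'. ``transmural_offset`` (Pa)
    raises the whole network pressure head above the interstitium: the
    default puts the venous end at 15 mmHg and the feeding arteriole at
    45 mmHg over the interstitium (physiological microvascular
    pressures). The domain is a small tissue window embedded in
    normothermic perfused host tissue: its edges exchange heat with a
    Robin coefficient equal to the conduction-perfusion screening
    conductance of the surroundings, h = sqrt(kappa * rho * cp * w_host),
    with a normal host perfusion rate ``w_host``.
    """
    if perfusion_model not in ("discrete", "lumped", "none"):
        raise ValueError("perfusion_model must be 'discrete', 'lumped' or 'none'")
    protocol = protocol or Protocol(omega_v_injected=omega_inj)
    solver = solver or SolverConfig(dt=protocol.dt, t_end=protocol.t_end)
    tparams = tparams or TransportParams()
    thermal = thermal or ThermalParams(
        SAR=SAR, beta_T=beta_T, w=w if perfusion_model == "lumped" else 0.0)

    grid = make_grid(nx, ny, Lx, Ly)
    if state is None:
        state = spherical_tumour_state(grid, r_tumour, centre, host_eps_v=0.0)
        # discrete mode: the homogenised vasculature is absent (eps_v=0);
        # pressures keep the tumour hallmarks
    if network is None:
        network = calibrated_network((0, 0, Lx, Ly), length_density, seed=network_seed)
    from .vasculature import replace_network

    # physiological microvascular pressures relative to the interstitium:
    # venular outlets ~15 mmHg, the feeding arteriole ~45 mmHg
    offset = 15.0 * MMHG_TO_PA if transmural_offset is None else transmural_offset
    head = 30.0 * MMHG_TO_PA
    network = replace_network(
        network,
        inlet_pressure=offset + head,
        outlet_pressure=offset,
    )
    net = collapse_vessels(network, state, St_threshold=0.5)
    net = solve_network_flow(net)

    h_line = min(grid.hx, grid.hy)
    mesh = build_vessel_mesh(net, h_line)
    coupling = build_line_coupling(grid, mesh.points[mesh.elems[:, 0]],
                                   mesh.points[mesh.elems[:, 1]])
    vessel = VesselTransport1D(mesh, solver.dt, tparams.D_NP, rho_v=tparams.rho_v)

    transport = NPTransportStepper(grid, state, tparams, solver.dt,
                                   mode="discrete", linear_rtol=solver.linear_rtol,
                                   outflow_edges=("left", "right", "bottom", "top"))
    h_embed = float(np.sqrt(thermal.kappa * thermal.rho * thermal.cp * w_host))
    boundary = {e: EdgeSpec("robin", h=h_embed, value=thermal.T_b)
                for e in ("left", "right", "bottom", "top")}
    heat = HeatStepper(
        grid, state, thermal, tparams, solver.dt, boundary,
        line=coupling if perfusion_model == "discrete" else None,
        line_radii=mesh.radii if perfusion_model == "discrete" else None,
        linear_rtol=solver.linear_rtol,
    )

    # per-1D-element static data for exchange
    R_e = mesh.radii
    pv_e = 0.5 * (net.pressures[mesh.net.segments[mesh.parent_segment][:, 0]]
                  + net.pressures[mesh.net.segments[mesh.parent_segment][:, 1]])
    pl_e = coupling.element_average(coupling.sample_field(state.pl))

    sim = SimState(grid=grid, T=np.full(grid.n_nodes, thermal.T_b))
    om_vessel = np.zeros(len(mesh.points))
    V = grid.nodal_volumes()
    series = {k: [] for k in ("times", "T_avg", "T_max", "T_min",
                              "tissue_np_mass", "vessel_np_mass")}
    snapshots, profiles = {}, {}

    def vessel_mass(om):
        return float(np.sum(vessel.storage * om))

    _series_append(series, 0.0, sim.T, V, transport.total_mass(sim.omega_l),
                   vessel_mass(om_vessel))

    t = 0.0
    for _ in range(solver.n_steps):
        t += solver.dt
        inlet_om = protocol.omega_v_at(t)

        om_l = sim.omega_l
        om_v = om_vessel
        for sweep in range(solver.max_sweeps):
            om_l_line = coupling.element_average(coupling.sample_field(om_l))
            om_v_e = 0.5 * (om_v[mesh.elems[:, 0]] + om_v[mesh.elems[:, 1]])
            m_line = transvascular_exchange_discrete(
                R_e, pv_e, om_v_e, pl_e, om_l_line, tparams)
            m_line = np.clip(m_line, 0.0, None)  # one-way: vessel -> tissue
            om_v_new, _ = vessel.step(om_vessel, inlet_om, m_line)
            om_l_new = transport.step(sim.omega_l, line_load=coupling.spread(m_line))
            rel = (np.linalg.norm(om_l_new - om_l)
                   / max(np.linalg.norm(om_l_new), 1e-300))
            om_l, om_v = om_l_new, om_v_new
            if rel < solver.fp_rtol:
                break
        sim.omega_l, om_vessel = om_l, om_v

        amf = protocol.amf_on(t)
        Qp = heat_source(state, sim, thermal, tparams, amf_on=amf)
        om_v_e = 0.5 * (om_vessel[mesh.elems[:, 0]] + om_vessel[mesh.elems[:, 1]])
        q_line = vessel_line_heat_source(R_e, om_v_e, thermal,
                                         rho_v=tparams.rho_v, amf_on=amf)
        sim.T = heat.step(sim.T, Qp, line_heat_load=coupling.spread(q_line))
        sim.t = t

        _series_append(series, t, sim.T, V, transport.total_mass(sim.omega_l),
                       vessel_mass(om_vessel))
        if abs(t - protocol.t_end) < 1e-9 or abs(t - 2400.0) < 1e-9:
            snapshots[t] = {"T": sim.T.copy(), "omega_l": sim.omega_l.copy()}

    j = grid.nearest_row(profile_y)
    nxp = grid.nx + 1
    row = slice(j * nxp, (j + 1) * nxp)
    profiles[f"T_y{profile_y}"] = (grid.nodes[row, 0].copy(),
                                   snapshots[protocol.t_end]["T"][row].copy())

    config = {"scenario": "discrete", "beta_T": beta_T, "perfusion_model": perfusion_model,
              "network_seed": network_seed, "w": w, "nx": nx, "ny": ny,
              "Lx": Lx, "Ly": Ly, "r_tumour": r_tumour,
              "length_density": length_density, "omega_inj": omega_inj, "SAR": SAR,
              "protocol": asdict(protocol)}
    res = _finish(series, snapshots, profiles, grid, config, seed=network_seed)
    res.network = net
    return res


# ---------------------------------------------------------------------------
# Scenario 3: mouse-leg tumour, prescribed nanoparticle distribution
# ---------------------------------------------------------------------------


MOUSE_T_B = 29.0 + CELSIUS


def run_mouse(distribution: str = "homogeneous", seed: int = 0, *,
              nx: int = 150, ny: int = 150, Lx: float = 9.5, Ly: float = 9.5,
              a: float = 4.0, b: float = 2.0,
              omega_tumour: float = 2.0e-3, SAR: float = 109.8,
              n_clusters: int = 4, cluster_radius: float = 0.6,
              t_end: float = 1800.0, dt: float = 60.0,
              thermal: ThermalParams | None = None,
              tparams: TransportParams | None = None,
              solver: SolverConfig | None = None,
              body_edges: tuple = ()) -> RunResult:
    """Mouse-leg scenario: elliptical tumour, prescribed interstitial
    nanoparticle field, temperature-only solve from a 29 degC baseline.

    ``distribution``: 'homogeneous' (omega uniform in the tumour) or
    'clustered' (four discs holding the same integrated nanoparticle
    mass). The leg protrudes into air, so all four edges exchange heat
    with the low air coefficient by default; pass ``body_edges`` (e.g.
    ``("bottom",)``) to give edges tissue-contact exchange instead.
    """
    if distribution not in ("homogeneous", "clustered"):
        raise ValueError("distribution must be 'homogeneous' or 'clustered'")
    thermal = thermal or ThermalParams(SAR=SAR, w=0.0, T_b=MOUSE_T_B)
    tparams = tparams or TransportParams()
    solver = solver or SolverConfig(dt=dt, t_end=t_end)

    grid = make_grid(nx, ny, Lx, Ly)
    state = ellipse_tumour_state(grid, a, b, (Lx / 2, Ly / 2))
    mask = tumour_mask(state)

    omega = np.where(mask, omega_tumour, 0.0)
    if distribution == "clustered":
        omega = clustered_np_field(grid, mask, n_clusters, cluster_radius,
                                   omega, seed, state=state)

    boundary = {
        e: EdgeSpec("robin",
                    h=thermal.h_tissue if e in body_edges else thermal.h_air,
                    value=thermal.T_b)
        for e in ("left", "right", "bottom", "top")
    }
    heat = HeatStepper(grid, state, thermal, tparams, solver.dt, boundary,
                       linear_rtol=solver.linear_rtol)
    sim = SimState(grid=grid, omega_l=omega, T=np.full(grid.n_nodes, thermal.T_b))
    Qp = heat_source(state, sim, thermal, tparams, amf_on=True)

    V = grid.nodal_volumes()
    series = {k: [] for k in ("times", "T_avg", "T_max", "T_min",
                              "tissue_np_mass", "vessel_np_mass")}
    m_np = float(np.sum(tparams.rho_l * state.eps * state.Sl * omega * V))
    snapshots, profiles = {}, {}
    _series_append(series, 0.0, sim.T, V, m_np, 0.0)

    t = 0.0
    for _ in range(solver.n_steps):
        t += solver.dt
        sim.T = heat.step(sim.T, Qp)
        _series_append(series, t, sim.T, V, m_np, 0.0)
    snapshots[t] = {"T": sim.T.copy(), "omega_l": omega.copy()}

    config = {"scenario": "mouse", "distribution": distribution, "seed": seed,
              "nx": nx, "ny": ny, "a": a, "b": b, "omega_tumour": omega_tumour,
              "SAR": SAR, "t_end": t_end, "dt": dt}
    return _finish(series, snapshots, profiles, grid, config, seed=seed)


# ---------------------------------------------------------------------------


def summarise(result: RunResult, reference: RunResult | None = None,
              spread_time: float | None = None) -> dict:
    """Peak temperatures, field spread, and cooling deltas vs a reference.

    Temperatures are reported in degC. The field spread (max - min over
    nodes) is evaluated at ``spread_time`` (default: the last snapshot).
    """
    if len(result.times) == 0:
        raise ValueError("empty time series")
    peak_avg, t_peak = result.peak_avg()
    out = {
        "peak_avg_C": peak_avg - CELSIUS,
        "t_peak_s": t_peak,
        "peak_point_C": float(result.T_max.max()) - CELSIUS,
    }
    if result.snapshots:
        ts = spread_time if spread_time is not None else max(result.snapshots)
        out["spread_C"] = result.spread_at(ts)
        out["spread_time_s"] = ts
    if reference is not None:
        if reference.grid.shape != result.grid.shape:
            raise ValueError("cannot difference runs on mismatched grids")
        out["delta_peak_avg_C"] = (reference.peak_avg()[0] - peak_avg)
        out["delta_peak_point_C"] = float(reference.T_max.max() - result.T_max.max())
        common = sorted(set(result.snapshots) & set(reference.snapshots))
        if common:
            tc = common[-1]
            dT = reference.snapshots[tc]["T"] - result.snapshots[tc]["T"]
            out["max_pointwise_cooling_C"] = float(dT.max())
        for label in set(result.profiles) & set(reference.profiles):
            x, v = result.profiles[label]
            _, vr = reference.profiles[label]
            out[f"max_profile_cooling_C[{label}]"] = float(np.max(vr - v))
    return out
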