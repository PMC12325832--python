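"""Bioheat transfer with SAR heating and perfusion cooling.

A single temperature is shared by all phases (local thermal equilibrium),
so the summed energy balance is solved:

    (cp rho)_eff dT/dt + cp_l rho_l q . grad T - div(kappa_eff grad T)
        = Qp - Qbl

with effective properties (cp rho)_eff = sum_g cp_g rho_g eps_g and
kappa_eff = sum_g kappa_g eps_g over solid, the three pore fluids and the
vasculature. The heat source Qp is SAR-proportional to the local
nanoparticle mass per volume (vascular + interstitial + discrete-vessel
line contribution). The perfusion sink Qbl is either the lumped Pennes
form rho_v cp_v w (T - Tb) or, with a resolved microvasculature, a line
sink 2 pi R beta_T (T - Tb) concentrated on the vessel centrelines
(blood isothermal at Tb). Robin edges exchange heat with surrounding
tissue at Tb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fem import (LineCoupling, LinearSolver, assemble_advection,
                  assemble_mass, assemble_robin, assemble_stiffness, edge_nodes)
from .grid import Grid2D
from .microenv import TissueState
from .transport import SimState, TransportParams

__all__ = [
    "ThermalParams",
    "effective_properties",
    "heat_source",
    "pennes_sink",
    "discrete_sink",
    "steady_0d_pennes",
    "HeatStepper",
]

T_BODY = 310.15  # K (37 degC)


@dataclass
class ThermalParams:
    """Thermal parameters in g-mm-s-K-W units.

    cp in J/(g K) (3470 J/(kg K) -> 3.47), kappa in W/(mm K), SAR in W/g
    (2.0 MW/kg -> 2000), perfusion rate w in 1/s, wall heat-exchange
    coefficient beta_T and boundary coefficients h in W/(mm^2 K). All
    phases share cp and kappa by default (printed tissue values).
    """

    cp: float = 3.47  # J/(g K), identical for all phases
    kappa: float = 0.51e-3  # W/(mm K), identical for all phases
    rho: float = 1e-3  # g/mm^3, all phases (water-like)
    SAR: float = 2000.0  # W/g
    w: float = 0.0  # 1/s, Pennes perfusion rate
    beta_T: float = 2e-5  # W/(mm^2 K), vessel-wall heat exchange
    h_tissue: float = 2e-5  # W/(mm^2 K)
    h_air: float = 0.3e-5  # W/(mm^2 K)
    T_b: float = T_BODY  # K

    def __post_init__(self):
        for name in ("cp", "kappa", "rho", "SAR", "w", "beta_T", "h_tissue", "h_air"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.T_b <= 0:
            raise ValueError("T_b must be positive (absolute temperature)")


def effective_properties(state: TissueState, params: ThermalParams,
                         cp_by_phase: dict | None = None,
                         kappa_by_phase: dict | None = None,
                         rho_by_phase: dict | None = None):
    """Volume-fraction-weighted (cp rho)_eff and kappa_eff per node.

    Phases: 's' (ECM solid, eps_s = 1 - eps - eps_v), 't', 'h', 'l'
    (pore fluids, eps * S), 'v' (vasculature, eps_v). Per-phase overrides
    are optional; by default all phases share the tissue values, in which
    case the sums collapse to cp*rho and kappa exactly.
    """
    eps_s = 1.0 - state.eps - state.eps_v
    fractions = {
        "s": eps_s,
        "t": state.eps * state.St,
        "h": state.eps * state.Sh,
        "l": state.eps * state.Sl,
        "v": state.eps_v,
    }
    cp_rho = np.zeros(state.grid.n_nodes)
    kappa = np.zeros(state.grid.n_nodes)
    for ph, frac in fractions.items():
        cp = (cp_by_phase or {}).get(ph, params.cp)
        kp = (kappa_by_phase or {}).get(ph, params.kappa)
        rho = (rho_by_phase or {}).get(ph, params.rho)
        cp_rho = cp_rho + cp * rho * frac
        kappa = kappa + kp * frac
    return cp_rho, kappa


def heat_source(state: TissueState, sim: SimState, params: ThermalParams,
                tparams: TransportParams | None = None, amf_on: bool = True) -> np.ndarray:
    """Volumetric SAR heat source Qp (W/mm^3), zero when the alternating
    magnetic field is off. Discrete-vessel line contributions are handled
    separately (see :func:`vessel_line_heat_source`)."""
    if not amf_on:
        return np.zeros(state.grid.n_nodes)
    rho_v = tparams.rho_v if tparams is not None else 1e-3
    rho_l = tparams.rho_l if tparams is not None else 1e-3
    np_mass = (rho_v * state.eps_v * sim.omega_v
               + rho_l * state.eps * state.Sl * sim.omega_l)
    return np_mass * params.SAR


def vessel_line_heat_source(radii: np.ndarray, omega_v_hat: np.ndarray,
                            params: ThermalParams, rho_v: float = 1e-3,
                            amf_on: bool = True) -> np.ndarray:
    """Line-density heat source rho_v pi R^2 omega_v SAR (W/mm) of
    nanoparticles flowing in discrete vessels."""
    if not amf_on:
        return np.zeros_like(np.asarray(radii, float))
    return rho_v * np.pi * np.asarray(radii) ** 2 * np.asarray(omega_v_hat) * params.SAR


def pennes_sink(sim: SimState, params: ThermalParams, rho_v: float = 1e-3) -> np.ndarray:
    """Lumped Pennes perfusion sink rho_v cp_v w (T - Tb) (W/mm^3);
    positive where the tissue is hotter than blood."""
    return rho_v * params.cp * params.w * (sim.T - params.T_b)


def discrete_sink(radii: np.ndarray, T_line: np.ndarray, params: ThermalParams) -> np.ndarray:
    """Line-density perfusion sink 2 pi R beta_T (T - Tb) (W/mm) along
    (uncollapsed) vessel centrelines; blood is isothermal at Tb."""
    return 2.0 * np.pi * np.asarray(radii) * params.beta_T * (np.asarray(T_line) - params.T_b)


def steady_0d_pennes(Qp: float, params: ThermalParams, rho_v: float = 1e-3) -> float:
    """Steady temperature of the space-free Pennes balance,
    Tb + Qp / (rho_v cp_v w); requires w > 0."""
    if params.w <= 0:
        raise ValueError("no steady state without perfusion (w must be > 0)")
    return params.T_b + Qp / (rho_v * params.cp * params.w)


class HeatStepper:
    """Backward-Euler stepper for the summed-phase energy balance.

    ``boundary`` maps each edge ('left', 'right', 'bottom', 'top') to an
    :class:`EdgeSpec` (robin / noflux / dirichlet). The optional line
    coupling adds an implicit discrete perfusion sink (matrix form, so it
    is unconditionally stable) and receives per-step vessel line heat
    sources. The Pennes sink is applied uniformly over the domain.
    """

    def __init__(self, grid: Grid2D, state: TissueState, params: ThermalParams,
                 tparams: TransportParams, dt: float, boundary: dict,
                 line: LineCoupling | None = None,
                 line_radii: np.ndarray | None = None,
                 pennes_eps_v_weighted: bool = False,
                 linear_rtol: float = 1e-10):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.state = state
        self.params = params
        self.tparams = tparams
        self.dt = dt
        self.line = line

        cp_rho, kappa = effective_properties(state, params)
        self.cp_rho_eff = cp_rho
        self.M = assemble_mass(grid, cp_rho)
        self.K = assemble_stiffness(grid, kappa)
        from .transport import darcy_velocity

        q = darcy_velocity(state, tparams)
        self.A = assemble_advection(grid, params.cp * tparams.rho_l, q)
        self.R, self.r_load = assemble_robin(grid, boundary)

        w_field = params.w * (state.eps_v / np.maximum(state.eps_v.max(), 1e-300)
                              if pennes_eps_v_weighted else 1.0)
        pennes_coeff = tparams.rho_v * params.cp * w_field
        self.P = assemble_mass(grid, pennes_coeff)
        self.pennes_coeff = pennes_coeff

        if line is not None:
            if line_radii is None:
                raise ValueError("line_radii required with a line coupling")
            coeff = 2.0 * np.pi * np.asarray(line_radii) * params.beta_T
            self.S_line = line.line_reaction_matrix(coeff)
        else:
            self.S_line = sp.csr_matrix((grid.n_nodes, grid.n_nodes))

        self.V = grid.nodal_volumes()
        Asys = (self.M.multiply(1.0 / dt) + self.K + self.A + self.R
                + self.P + self.S_line).tolil()

        self.dirichlet_nodes = np.empty(0, int)
        self.dirichlet_values = np.empty(0)
        dir_nodes, dir_vals = [], []
        for name, spec in boundary.items():
            if spec.kind == "dirichlet":
                ids = edge_nodes(grid, name)
                dir_nodes.append(ids)
                dir_vals.append(np.full(len(ids), spec.value))
        if dir_nodes:
            self.dirichlet_nodes = np.concatenate(dir_nodes)
            self.dirichlet_values = np.concatenate(dir_vals)
            for i, val in zip(self.dirichlet_nodes, self.dirichlet_values):
                Asys.rows[i] = [int(i)]
                Asys.data[i] = [1.0]
        self.solver = LinearSolver(Asys.tocsr(), rtol=linear_rtol)
        self.ledger = {"source": 0.0, "pennes": 0.0, "line_sink": 0.0,
                       "boundary": 0.0}

    def step(self, T: np.ndarray, Qp_nodal: np.ndarray,
             line_heat_load: np.ndarray | None = None) -> np.ndarray:
        """Advance T one backward-Euler step with volumetric source
        ``Qp_nodal`` (W/mm^3) and optional pre-spread line heat load."""
        p = self.params
        b = (self.M.multiply(1.0 / self.dt)) @ T
        b = b + Qp_nodal * self.V
        b = b + self.r_load  # Robin reference flux h*Tb
        b = b + self.P @ np.full_like(T, p.T_b)
        b = b + self.S_line @ np.full_like(T, p.T_b)
        if line_heat_load is not None:
            b = b + line_heat_load
        if len(self.dirichlet_nodes):
            b[self.dirichlet_nodes] = self.dirichlet_values
        new = self.solver.solve(b)

        self.ledger["source"] += float(np.sum(Qp_nodal * self.V)) * self.dt
        self.ledger["pennes"] += float(np.sum(self.P @ (new - p.T_b))) * self.dt
        self.ledger["line_sink"] += float(np.sum(self.S_line @ (new - p.T_b))) * self.dt
        self.ledger["boundary"] += float(np.sum(self.R @ new - self.r_load)) * self.dt
        return new
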