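"""Interstitial nanoparticle transport.

The nanoparticle mass fraction omega_l in the interstitial fluid (IF)
obeys a diffusion-advection balance with pore-volume-weighted storage
(eps*S_l*rho_l), Darcy advection from the frozen IF pressure field,
transvascular exchange (Starling-type convective drag through the leaky
endothelium plus diffusive wall permeation, one-way vasculature -> IF),
and lymphatic drainage that shuts off where the cell-phase pressure
exceeds the lymphatic collapse pressure.

Exchange comes in two forms mirroring the two vasculature models:
homogenised (volumetric, scaled by eps_v * S/V) and discrete (per unit
vessel length, scaled by the circumference 2 pi R, concentrated on the
centreline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fem import (LinearSolver, assemble_advection_conservative,
                  assemble_mass, assemble_stiffness)
from .grid import Grid2D
from .microenv import TissueState

__all__ = [
    "TransportParams",
    "SimState",
    "darcy_velocity",
    "transvascular_exchange_homogenised",
    "transvascular_exchange_discrete",
    "lymphatic_drainage",
    "NPTransportStepper",
]

MEAN_CAPILLARY_RADIUS = 6.98e-3  # mm


@dataclass
class TransportParams:
    """Nanoparticle-transport parameters (g-mm-s units).

    Defaults are the published nanoparticle-hyperthermia set: diffusivity,
    wall permeability, wall hydraulic conductivity and the lymphatic
    filtration coefficient; the homogenised surface-to-volume ratio is the
    cylinder value 2/R at the mean capillary radius, and the oncotic term
    defaults to zero.
    """

    D_NP: float = 1.2955e-5  # mm^2/s, NP diffusivity in the IF
    P_v: float = 2.0e-6  # mm/s, vessel-wall permeability
    Lp_v: float = 1.0e-7  # mm^2 s/g, vessel-wall hydraulic conductivity
    sigma: float = 0.0  # oncotic reflection coefficient
    pi_v: float = 0.0  # Pa
    pi_l: float = 0.0  # Pa
    SoverV: float = 2.0 / MEAN_CAPILLARY_RADIUS  # 1/mm, vessel surface/volume
    LpSoverV_ly: float = 1.04e-6  # 1/(Pa s), lymphatic filtration coefficient
    p_ly: float = 0.0  # Pa, lymphatic pressure
    p_coll_ly: float = 1066.58  # Pa (8 mmHg), lymphatic collapse pressure
    # IF mobility k_l/mu_l from the intrinsic ECM permeability (~1e-18 m^2)
    # over the IF viscosity; advection is a weak effect next to diffusion
    k_over_mu: float = 1.0e-9  # mm^3 s/g
    rho_l: float = 1e-3  # g/mm^3
    rho_v: float = 1e-3  # g/mm^3
    #: concentration carried by the interendothelial (solvent-drag) flux:
    #: 'upwind' takes the upstream side of the transmural flow (vessel
    #: concentration during filtration), the standard high-wall-Peclet
    #: limit; 'mean' takes the arithmetic wall average
    drag_concentration: str = "upwind"

    def __post_init__(self):
        for name in ("D_NP", "P_v", "Lp_v", "pi_v", "pi_l", "SoverV",
                     "LpSoverV_ly", "k_over_mu", "rho_l", "rho_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")
        if self.drag_concentration not in ("upwind", "mean"):
            raise ValueError("drag_concentration must be 'upwind' or 'mean'")
        if self.p_coll_ly == 0:
            raise ValueError("p_coll_ly must be non-zero (impairment divides by it)")


@dataclass
class SimState:
    """Evolving primary fields on the grid."""

    grid: Grid2D
    omega_l: np.ndarray = None  # interstitial NP mass fraction
    omega_v: np.ndarray = None  # homogenised vascular NP mass fraction
    v_darcy: np.ndarray = None  # (n, 2) IF Darcy flux, mm/s
    T: np.ndarray = None  # temperature, K
    t: float = 0.0

    def __post_init__(self):
        n = self.grid.n_nodes
        if self.omega_l is None:
            self.omega_l = np.zeros(n)
        if self.omega_v is None:
            self.omega_v = np.zeros(n)
        if self.v_darcy is None:
            self.v_darcy = np.zeros((n, 2))
        if self.T is None:
            self.T = np.full(n, 310.15)
        for name in ("omega_l", "omega_v", "T"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape == ():
                arr = np.full(n, float(arr))
            setattr(self, name, arr)

    def validate(self):
        if (self.omega_l < 0).any():
            raise ValueError("omega_l must be non-negative")
        if (self.T < 0).any():
            raise ValueError("temperature below absolute zero")


def darcy_velocity(state: TissueState, params: TransportParams) -> np.ndarray:
    """Nodal IF Darcy flux v = -(k/mu) grad(p_l), by lattice gradient
    recovery (central differences inside, one-sided at edges)."""
    g = state.grid
    p = g.as_lattice(state.pl)
    gx = np.gradient(p, g.hx, axis=1)
    gy = np.gradient(p, g.hy, axis=0)
    v = -params.k_over_mu * np.column_stack([gx.ravel(), gy.ravel()])
    return v


def _starling_pressure(state: TissueState, params: TransportParams,
                       pv=None, pl=None) -> np.ndarray:
    pv = state.pv if pv is None else pv
    pl = state.pl if pl is None else pl
    return pv - pl - params.sigma * (params.pi_v - params.pi_l)


def transvascular_exchange_homogenised(state: TissueState, sim: SimState,
                                       params: TransportParams) -> np.ndarray:
    """Volumetric NP mass source (g/(mm^3 s)) from the homogenised
    vasculature: convective interendothelial drag plus one-way diffusive
    transendothelial permeation."""
    dp = _starling_pressure(state, params)
    coeff = params.rho_v * state.eps_v * params.SoverV
    m_inter = coeff * params.Lp_v * dp * _drag_omega(dp, sim.omega_v, sim.omega_l,
                                                    params.drag_concentration)
    m_trans = coeff * params.P_v * np.clip(sim.omega_v - sim.omega_l, 0.0, None)
    return m_inter + m_trans


def _drag_omega(dp, omega_v, omega_l, mode: str):
    """Concentration carried by the transmural filtration flow."""
    if mode == "mean":
        return 0.5 * (np.asarray(omega_v) + np.asarray(omega_l))
    return np.where(np.asarray(dp) >= 0, omega_v, omega_l)


def transvascular_exchange_discrete(radii: np.ndarray, pv_hat: np.ndarray,
                                    omega_v_hat: np.ndarray, pl_line: np.ndarray,
                                    omega_l_line: np.ndarray,
                                    params: TransportParams,
                                    collapsed: np.ndarray | None = None) -> np.ndarray:
    """Line-density NP mass source (g/(mm s)) along vessel elements.

    Inputs are per-1D-element (or per-quadrature-point) values: vessel
    radius, blood pressure and mass fraction on the centreline, and tissue
    pressure/mass fraction interpolated to the centreline. The identical
    magnitude must be removed from the 1D vessel mass by the caller
    (ledger balance). Collapsed elements contribute exactly zero.
    """
    dp = pv_hat - pl_line - params.sigma * (params.pi_v - params.pi_l)
    circ = 2.0 * np.pi * np.asarray(radii)
    m_inter = params.rho_v * circ * params.Lp_v * dp * _drag_omega(
        dp, omega_v_hat, omega_l_line, params.drag_concentration)
    m_trans = params.rho_v * circ * params.P_v * np.clip(omega_v_hat - omega_l_line, 0.0, None)
    out = m_inter + m_trans
    if collapsed is not None:
        out = np.where(np.asarray(collapsed, bool), 0.0, out)
    return out


def lymphatic_drainage(state: TissueState, sim: SimState,
                       params: TransportParams) -> np.ndarray:
    """Volumetric NP mass sink (g/(mm^3 s)) into the lymphatics; always
    >= 0, and zero wherever the cell pressure reaches the collapse
    pressure (impaired drainage) or the IF pressure is below lymphatic
    pressure."""
    return drainage_coefficient(state, params) * sim.omega_l


def drainage_coefficient(state: TissueState, params: TransportParams) -> np.ndarray:
    """Drainage rate coefficient multiplying omega_l (g/(mm^3 s))."""
    impair = np.clip(1.0 - state.pt / params.p_coll_ly, 0.0, None)
    return (params.rho_l * params.LpSoverV_ly
            * np.clip(state.pl - params.p_ly, 0.0, None) * impair)


class NPTransportStepper:
    """Backward-Euler stepper for the interstitial NP mass fraction.

    All operators are constant over a run (frozen microenvironment), so
    the system matrix is factorised once. The linear-in-omega_l parts of
    exchange (the convective drag's omega_l/2) and drainage sit in the
    matrix; the clamped transendothelial term is handled by Picard
    iteration in the caller's fixed-point sweeps (it converges to the
    fully implicit backward-Euler solution).

    Mode 'homogenised': omega_v is a prescribed Dirichlet-in-time value.
    Mode 'discrete': line sources are passed per step via ``line_load``.
    """

    def __init__(self, grid: Grid2D, state: TissueState, params: TransportParams,
                 dt: float, mode: str = "homogenised", linear_rtol: float = 1e-10,
                 outflow_edges: tuple = ()):
        if mode not in ("homogenised", "discrete"):
            raise ValueError("mode must be 'homogenised' or 'discrete'")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.state = state
        self.params = params
        self.dt = dt
        self.mode = mode

        storage = state.eps * state.Sl * params.rho_l
        self.storage = storage
        self.M = assemble_mass(grid, storage)
        diff = params.rho_l * state.eps * state.Sl * params.D_NP
        self.K = assemble_stiffness(grid, diff)
        # conservative upwind advection with the Darcy flux of the IF:
        # the frozen pressure field has div(q) != 0 (unmodelled fluid
        # exchange), and the conservative form keeps the nanoparticle
        # ledger closed instead of destroying mass where the flow slows
        self.A = assemble_advection_conservative(grid, params.rho_l, state.pl,
                                                 params.k_over_mu,
                                                 outflow_edges=outflow_edges)
        self.v_darcy = darcy_velocity(state, params)

        self.drain_coeff = drainage_coefficient(state, params)
        self.D = assemble_mass(grid, self.drain_coeff)  # diag sink matrix

        dp = _starling_pressure(state, params)
        ex_coeff = params.rho_v * state.eps_v * params.SoverV
        self.inter_coeff = ex_coeff * params.Lp_v * dp  # * drag concentration
        self.trans_coeff = ex_coeff * params.P_v  # * (omega_v-omega_l)_+
        if self.mode == "discrete":
            self.inter_coeff = np.zeros_like(self.inter_coeff)
            self.trans_coeff = np.zeros_like(self.trans_coeff)

        V = grid.nodal_volumes()
        self.V = V
        # the omega_l-proportional share of the drag term goes in the
        # matrix (implicit): half of it in 'mean' mode; in 'upwind' mode
        # only where the transmural pressure is negative (re-absorption)
        if params.drag_concentration == "mean":
            self._inter_matrix_coeff = 0.5 * self.inter_coeff
            self._inter_source_coeff = 0.5 * self.inter_coeff
        else:
            self._inter_matrix_coeff = np.where(self.inter_coeff < 0,
                                                self.inter_coeff, 0.0)
            self._inter_source_coeff = np.clip(self.inter_coeff, 0.0, None)
        Inter_l = sp.diags(self._inter_matrix_coeff * V)
        Asys = self.M.multiply(1.0 / dt) + self.K + self.A + self.D - Inter_l
        self.solver = LinearSolver(Asys.tocsr(), rtol=linear_rtol)

        # cumulative mass ledger (g)
        self.ledger = {"exchange": 0.0, "drainage": 0.0, "advection": 0.0,
                       "line_exchange": 0.0}

    def total_mass(self, omega_l: np.ndarray) -> float:
        return float(np.sum(self.storage * self.V * omega_l))

    def step(self, omega_l: np.ndarray, omega_v_value: float = 0.0,
             line_load: np.ndarray | None = None,
             omega_l_guess: np.ndarray | None = None) -> np.ndarray:
        """Advance omega_l one backward-Euler step.

        ``omega_v_value``: homogenised vascular Dirichlet mass fraction at
        the new time level. ``line_load``: pre-spread 2D load vector
        (g/(mm^3 s) * volume -> g/s nodal rates) of discrete line sources.
        ``omega_l_guess``: Picard iterate for the clamped term (defaults
        to the old field).
        """
        guess = omega_l if omega_l_guess is None else omega_l_guess
        b = (self.M.multiply(1.0 / self.dt)) @ omega_l
        src = np.zeros(self.grid.n_nodes)
        if self.mode == "homogenised":
            omega_v = np.where(self.state.eps_v > 0, omega_v_value, 0.0)
            src += self._inter_source_coeff * omega_v
            src += self.trans_coeff * np.clip(omega_v - guess, 0.0, None)
        b = b + src * self.V
        if line_load is not None:
            b = b + line_load
        new = self.solver.solve(b)

        # bookkeeping (implicit evaluation, consistent with the scheme)
        ex = float(np.sum((src + self._inter_matrix_coeff * new) * self.V)) * self.dt
        self.ledger["exchange"] += ex
        self.ledger["drainage"] += float(self.D @ new @ np.ones_like(new)) * self.dt
        self.ledger["advection"] += float(np.sum(self.A @ new)) * self.dt
        if line_load is not None:
            self.ledger["line_exchange"] += float(np.sum(line_load)) * self.dt
        return new
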