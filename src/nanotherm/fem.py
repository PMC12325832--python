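"""Numerical core: bilinear-quad FEM operators on structured grids,
Dirac line-source coupling to embedded 1D vessel meshes, and the
backward-Euler stepping configuration.

Design notes
------------
* Storage (mass) terms are lumped (trapezoidal nodal volumes) for
  boundedness; the stiffness matrix is the standard consistent bilinear
  form with element-wise constant coefficients (node average).
* Advection uses first-order upwind differences on the node lattice in
  non-conservative form c*(v.grad u), scaled by the lumped nodal volume.
  Together with backward Euler this keeps the system an M-matrix at any
  Peclet number and time step.
* Robin boundary terms are lumped along flagged edges.
* Linear systems are solved by sparse LU (`splu`); operators in this model
  are constant over a run, so each run factorises once and reuses the
  factor for every step. Residuals are checked against a relative
  tolerance and failure raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import Grid2D

__all__ = [
    "SolverConfig",
    "EdgeSpec",
    "assemble_mass",
    "assemble_stiffness",
    "assemble_advection",
    "assemble_robin",
    "LineCoupling",
    "build_line_coupling",
    "LinearSolver",
]

EDGES = ("left", "right", "bottom", "top")

_GAUSS_1D = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))


@dataclass
class SolverConfig:
    """Time-stepping and solver tolerances for a coupled run."""

    dt: float = 60.0  # s
    t_end: float = 3600.0  # s
    linear_rtol: float = 1e-10
    max_sweeps: int = 5  # fixed-point sweeps per step
    fp_rtol: float = 1e-8  # relative change stopping the sweeps
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.linear_rtol <= 0 or self.fp_rtol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def n_steps(self) -> int:
        n = self.t_end / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_end must be an integer multiple of dt")
        return int(round(n))


@dataclass
class EdgeSpec:
    """Boundary assignment for one grid edge.

    kind is 'robin' (coefficient h, reference Tref), 'noflux', or
    'dirichlet' (value).
    """

    kind: str
    h: float = 0.0
    value: float = 0.0


def _check_edges(boundary: dict) -> None:
    missing = [e for e in EDGES if e not in boundary]
    if missing:
        raise ValueError(f"boundary specification missing edges: {missing}")


def assemble_mass(grid: Grid2D, coeff) -> sp.csr_matrix:
    """Lumped mass matrix diag(coeff_i * V_i); row sums = nodal volumes
    for unit coefficient."""
    c = np.broadcast_to(np.asarray(coeff, float), (grid.n_nodes,))
    return sp.diags(c * grid.nodal_volumes()).tocsr()


def _element_stiffness(hx: float, hy: float) -> np.ndarray:
    """4x4 bilinear-quad stiffness for unit conductivity (CCW node order)."""
    a, b = hx / hy, hy / hx
    k = np.array(
        [
            [2 * (a + b), a - 2 * b, -(a + b), b - 2 * a],
            [a - 2 * b, 2 * (a + b), b - 2 * a, -(a + b)],
            [-(a + b), b - 2 * a, 2 * (a + b), a - 2 * b],
            [b - 2 * a, -(a + b), a - 2 * b, 2 * (a + b)],
        ]
    ) / 6.0
    return k


def assemble_stiffness(grid: Grid2D, coeff) -> sp.csr_matrix:
    """Stiffness for -div(coeff grad u); ``coeff`` nodal (averaged per
    element) or scalar. Symmetric positive semi-definite for coeff >= 0."""
    c = np.broadcast_to(np.asarray(coeff, float), (grid.n_nodes,))
    if (c < 0).any():
        raise ValueError("diffusion coefficient must be non-negative")
    ke = _element_stiffness(grid.hx, grid.hy)
    celem = c[grid.elements].mean(axis=1)  # element-wise constant coefficient
    ne = grid.n_elements
    rows = np.repeat(grid.elements, 4, axis=1).ravel()
    cols = np.tile(grid.elements, (1, 4)).ravel()
    vals = (celem[:, None, None] * ke[None, :, :]).reshape(ne, 16).ravel()
    K = sp.coo_matrix((vals, (rows, cols)), shape=(grid.n_nodes, grid.n_nodes))
    return K.tocsr()


def assemble_advection(grid: Grid2D, coeff, velocity: np.ndarray) -> sp.csr_matrix:
    """Upwind advection operator A with (A u)_i ~ V_i * c_i * (v.grad u)_i.

    ``velocity`` is nodal, shape (n_nodes, 2) in mm/s; ``coeff`` the
    multiplying density-capacity factor (e.g. rho_l or cp*rho of the
    moving phase times its volume-flux normalisation).
    """
    n = grid.n_nodes
    c = np.broadcast_to(np.asarray(coeff, float), (n,))
    v = np.asarray(velocity, float).reshape(n, 2)
    V = grid.nodal_volumes()
    nxp, hx, hy = grid.nx + 1, grid.hx, grid.hy

    rows, cols, vals = [], [], []
    idx = np.arange(n)
    i = idx % nxp
    j = idx // nxp

    def add(r, cidx, val):
        rows.append(r)
        cols.append(cidx)
        vals.append(val)

    # x-direction
    vx = v[:, 0] * c * V
    pos = (vx > 0) & (i > 0)
    add(idx[pos], idx[pos], vx[pos] / hx)
    add(idx[pos], idx[pos] - 1, -vx[pos] / hx)
    neg = (vx < 0) & (i < nxp - 1)
    add(idx[neg], idx[neg], -vx[neg] / hx)
    add(idx[neg], idx[neg] + 1, vx[neg] / hx)
    # nodes whose upwind neighbour lies outside the domain get no
    # contribution (zero upstream gradient, i.e. no-variation inflow)

    vy = v[:, 1] * c * V
    pos = (vy > 0) & (j > 0)
    add(idx[pos], idx[pos], vy[pos] / hy)
    add(idx[pos], idx[pos] - nxp, -vy[pos] / hy)
    neg = (vy < 0) & (j < grid.ny)
    add(idx[neg], idx[neg], -vy[neg] / hy)
    add(idx[neg], idx[neg] + nxp, vy[neg] / hy)

    rows = np.concatenate(rows) if rows else np.empty(0, int)
    cols = np.concatenate(cols) if cols else np.empty(0, int)
    vals = np.concatenate(vals) if vals else np.empty(0)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def assemble_advection_conservative(grid: Grid2D, coeff, pressure: np.ndarray,
                                    mobility: float,
                                    outflow_edges: tuple = ()) -> sp.csr_matrix:
    """Conservative finite-volume upwind operator for div(coeff * q * u)
    with the Darcy face flux q_f = -mobility * dp/dn taken directly from
    the nodal pressure differences (two-point flux, exactly divergence-
    consistent on the lattice, so interior advection conserves mass to
    round-off; the domain boundary is closed).
    """
    n = grid.n_nodes
    c = np.broadcast_to(np.asarray(coeff, float), (n,))
    p = np.asarray(pressure, float).ravel()
    nxp = grid.nx + 1
    lat = np.arange(n).reshape(grid.ny + 1, nxp)

    rows, cols, vals = [], [], []

    def upwind_faces(i_from, i_to, Q):
        """Face volumetric flow Q (signed from -> to); upwind the carried
        concentration and scatter conservative in/out terms."""
        pos = Q > 0
        neg = Q < 0
        f, t, q = i_from[pos], i_to[pos], Q[pos]
        rows.extend([f, t])
        cols.extend([f, f])
        vals.extend([0.5 * (c[f] + c[t]) * q, -0.5 * (c[f] + c[t]) * q])
        f, t, q = i_from[neg], i_to[neg], -Q[neg]
        rows.extend([t, f])
        cols.extend([t, t])
        vals.extend([0.5 * (c[f] + c[t]) * q, -0.5 * (c[f] + c[t]) * q])

    # x-faces between (i,j) and (i+1,j): area hy (half at top/bottom rows)
    ay = np.full(grid.ny + 1, grid.hy)
    ay[[0, -1]] = grid.hy / 2
    a = lat[:, :-1].ravel()
    b = lat[:, 1:].ravel()
    area = np.repeat(ay, grid.nx)
    Q = -mobility * (p[b] - p[a]) / grid.hx * area
    upwind_faces(a, b, Q)

    ax = np.full(grid.nx + 1, grid.hx)
    ax[[0, -1]] = grid.hx / 2
    a = lat[:-1, :].ravel()
    b = lat[1:, :].ravel()
    area = np.tile(ax, grid.ny)
    Q = -mobility * (p[b] - p[a]) / grid.hy * area
    upwind_faces(a, b, Q)

    # free-outflow edges: where the Darcy flux points outward (one-sided
    # pressure gradient), the carried mass leaves the domain
    for edge in outflow_edges:
        ids = edge_nodes(grid, edge)
        if edge == "left":
            inner, h = ids + 1, grid.hx
        elif edge == "right":
            inner, h = ids - 1, grid.hx
        elif edge == "bottom":
            inner, h = ids + nxp, grid.hy
        else:  # top
            inner, h = ids - nxp, grid.hy
        w = _edge_weights(grid, edge)
        q_n = -mobility * (p[ids] - p[inner]) / h  # outward normal flux
        out = np.clip(q_n, 0.0, None) * w
        rows.append(ids)
        cols.append(ids)
        vals.append(c[ids] * out)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def edge_nodes(grid: Grid2D, edge: str) -> np.ndarray:
    nxp = grid.nx + 1
    if edge == "left":
        return np.arange(0, grid.n_nodes, nxp)
    if edge == "right":
        return np.arange(nxp - 1, grid.n_nodes, nxp)
    if edge == "bottom":
        return np.arange(nxp)
    if edge == "top":
        return np.arange(grid.n_nodes - nxp, grid.n_nodes)
    raise ValueError(f"unknown edge {edge!r}")


def _edge_weights(grid: Grid2D, edge: str) -> np.ndarray:
    """Lumped boundary lengths per edge node (trapezoidal)."""
    h = grid.hy if edge in ("left", "right") else grid.hx
    n = grid.ny + 1 if edge in ("left", "right") else grid.nx + 1
    w = np.full(n, h)
    w[[0, -1]] = h / 2
    return w


def assemble_robin(grid: Grid2D, boundary: dict) -> tuple[sp.csr_matrix, np.ndarray]:
    """Robin matrix R and load r so the boundary term is R@u - r.

    ``boundary`` maps each edge name to an :class:`EdgeSpec`; only
    'robin' edges contribute (-kappa du/dn = h (u - value)).
    """
    _check_edges(boundary)
    n = grid.n_nodes
    diag = np.zeros(n)
    load = np.zeros(n)
    for edge, spec in boundary.items():
        if spec.kind != "robin":
            continue
        ids = edge_nodes(grid, edge)
        w = _edge_weights(grid, edge) * spec.h
        diag[ids] += w
        load[ids] += w * spec.value
    return sp.diags(diag).tocsr(), load


# ---------------------------------------------------------------------------
# Dirac line-source coupling between a 1D vessel mesh and the 2D grid
# ---------------------------------------------------------------------------


@dataclass
class LineCoupling:
    """Quadrature of the vessel centreline Lambda embedded in the grid.

    ``sample`` is the sparse (n_quad x n_nodes) bilinear interpolation
    matrix; spreading a per-length density q(s) to the 2D load vector is
    its transpose applied to (w * q): the two operators are exact adjoints
    by construction.
    """

    sample: sp.csr_matrix  # (n_q, n_nodes2d)
    weights: np.ndarray  # quadrature weights ds (mm), length n_q
    element_of_quad: np.ndarray  # 1D element index per quadrature point
    lengths: np.ndarray  # 1D element lengths (mm)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def spread(self, q_per_length: np.ndarray) -> np.ndarray:
        """2D load vector of the line density q (per quad point or per
        1D element)."""
        q = np.asarray(q_per_length, float)
        if q.shape == self.lengths.shape:
            q = q[self.element_of_quad]
        return self.sample.T @ (self.weights * q)

    def sample_field(self, nodal_field: np.ndarray) -> np.ndarray:
        """Values of a 2D nodal field at the quadrature points."""
        return self.sample @ np.asarray(nodal_field, float)

    def element_average(self, quad_values: np.ndarray) -> np.ndarray:
        """Average quad-point values per 1D element."""
        num = np.bincount(self.element_of_quad, weights=self.weights * quad_values,
                          minlength=len(self.lengths))
        return num / self.lengths

    def line_reaction_matrix(self, coeff_per_length) -> sp.csr_matrix:
        """Matrix for an implicit line sink coeff*(u - ref): L^T diag(w c) L."""
        c = np.asarray(coeff_per_length, float)
        if c.shape == self.lengths.shape:
            c = c[self.element_of_quad]
        c = np.broadcast_to(c, self.weights.shape)
        return (self.sample.T @ sp.diags(self.weights * c) @ self.sample).tocsr()


def build_line_coupling(grid: Grid2D, points0: np.ndarray, points1: np.ndarray) -> LineCoupling:
    """Couple 1D elements given by endpoint arrays to the 2D grid.

    Each 1D element gets two Gauss points; bilinear shape-function weights
    are evaluated in the host grid cell of each point.
    """
    p0 = np.asarray(points0, float).reshape(-1, 2)
    p1 = np.asarray(points1, float).reshape(-1, 2)
    lengths = np.hypot(*(p1 - p0).T)
    if (lengths <= 0).any():
        raise ValueError("zero-length 1D element in line coupling")

    qpts = []
    wts = []
    elem_of_q = []
    for g in _GAUSS_1D:
        t = 0.5 * (1 + g)
        qpts.append(p0 + t * (p1 - p0))
        wts.append(0.5 * lengths)
        elem_of_q.append(np.arange(len(lengths)))
    qpts = np.vstack(qpts)
    wts = np.concatenate(wts)
    elem_of_q = np.concatenate(elem_of_q)

    eps = 1e-12
    if (qpts[:, 0] < -eps).any() or (qpts[:, 0] > grid.Lx + eps).any() or \
       (qpts[:, 1] < -eps).any() or (qpts[:, 1] > grid.Ly + eps).any():
        raise ValueError("vessel segment lies outside the grid domain")

    x = np.clip(qpts[:, 0], 0, grid.Lx * (1 - 1e-15))
    y = np.clip(qpts[:, 1], 0, grid.Ly * (1 - 1e-15))
    ix = np.minimum((x / grid.hx).astype(int), grid.nx - 1)
    iy = np.minimum((y / grid.hy).astype(int), grid.ny - 1)
    xi = x / grid.hx - ix  # local coords in [0, 1]
    eta = y / grid.hy - iy

    nxp = grid.nx + 1
    n00 = iy * nxp + ix
    nodes = np.column_stack([n00, n00 + 1, n00 + nxp + 1, n00 + nxp])
    shp = np.column_stack(
        [(1 - xi) * (1 - eta), xi * (1 - eta), xi * eta, (1 - xi) * eta]
    )
    nq = len(x)
    rows = np.repeat(np.arange(nq), 4)
    L = sp.coo_matrix((shp.ravel(), (rows, nodes.ravel())), shape=(nq, grid.n_nodes))
    return LineCoupling(sample=L.tocsr(), weights=wts, element_of_quad=elem_of_q,
                        lengths=lengths)


class LinearSolver:
    """Sparse-LU solver with residual verification and factor reuse."""

    def __init__(self, A: sp.spmatrix, rtol: float = 1e-10):
        self.A = A.tocsc()
        self.rtol = rtol
        self._lu = spla.splu(self.A)

    def solve(self, b: np.ndarray) -> np.ndarray:
        x = self._lu.solve(b)
        nb = np.linalg.norm(b)
        res = np.linalg.norm(self.A @ x - b)
        if nb > 0 and res > self.rtol * max(nb, np.linalg.norm(self.A @ x)):
            raise RuntimeError(
                f"linear solve residual {res:.3e} exceeds rtol {self.rtol:g} (|b|={nb:.3e})"
            )
        return x
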