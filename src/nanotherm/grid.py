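"""Structured 2D grids of bilinear quadrilaterals.

All lengths are in mm (the package-wide unit system is g-mm-s-K-W, so that
1 Pa = 1 g/(mm*s^2) and pressures from the literature convert via
1 mmHg = 133.322 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid2D", "make_grid"]


@dataclass(frozen=True)
class Grid2D:
    """Regular lattice of ``nx`` x ``ny`` quadrilateral elements.

    Nodes are ordered row-major with x fastest: node index ``j*(nx+1)+i``
    sits at ``(i*hx, j*hy)``. Element connectivity is counter-clockwise.
    """

    nx: int
    ny: int
    Lx: float
    Ly: float
    nodes: np.ndarray = field(repr=False)  # (n_nodes, 2) coordinates in mm
    elements: np.ndarray = field(repr=False)  # (n_elem, 4) CCW node ids

    @property
    def hx(self) -> float:
        return self.Lx / self.nx

    @property
    def hy(self) -> float:
        return self.Ly / self.ny

    @property
    def n_nodes(self) -> int:
        return (self.nx + 1) * (self.ny + 1)

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        """Node lattice shape (ny+1, nx+1) for reshaping nodal fields."""
        return (self.ny + 1, self.nx + 1)

    def node_index(self, i: int, j: int) -> int:
        """Flat node id of lattice position (i, j), x index first."""
        return j * (self.nx + 1) + i

    def as_lattice(self, field: np.ndarray) -> np.ndarray:
        """View a flat nodal field as a (ny+1, nx+1) lattice array."""
        return np.asarray(field).reshape(self.shape)

    def nodal_volumes(self) -> np.ndarray:
        """Lumped nodal areas (trapezoidal weights); sums to Lx*Ly."""
        wx = np.full(self.nx + 1, self.hx)
        wx[[0, -1]] = self.hx / 2
        wy = np.full(self.ny + 1, self.hy)
        wy[[0, -1]] = self.hy / 2
        return (wy[:, None] * wx[None, :]).ravel()

    def nearest_row(self, y: float) -> int:
        """Lattice row index j whose y-coordinate is closest to ``y``."""
        return int(round(y / self.hy))


def make_grid(nx: int, ny: int, Lx: float, Ly: float) -> Grid2D:
    """Build a regular grid with ``nx*ny`` elements on ``[0,Lx]x[0,Ly]``."""
    if nx < 1 or ny < 1:
        raise ValueError(f"element counts must be >= 1, got nx={nx}, ny={ny}")
    if Lx <= 0 or Ly <= 0:
        raise ValueError(f"domain lengths must be > 0, got Lx={Lx}, Ly={Ly}")
    x = np.linspace(0.0, Lx, nx + 1)
    y = np.linspace(0.0, Ly, ny + 1)
    X, Y = np.meshgrid(x, y)
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    i = np.arange(nx)
    j = np.arange(ny)
    I, J = np.meshgrid(i, j)
    n0 = (J * (nx + 1) + I).ravel()
    elements = np.column_stack([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    return Grid2D(nx=nx, ny=ny, Lx=float(Lx), Ly=float(Ly), nodes=nodes, elements=elements)
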