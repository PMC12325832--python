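"""Synthetic frozen tumour-microenvironment states.

A grown solid tumour exhibits a handful of robust hallmarks: elevated
interstitial-fluid pressure (IFP) peaking at the centre, an avascular
(non-perfused) core where the growing mass has collapsed the capillaries,
and a vascularised host with a few-percent vascular volume fraction. The
generators here produce nodal fields with exactly those hallmarks on a
structured grid, standing in for a full multiphase growth simulation. The
radial profiles are smoothed steps (tanh) with a configurable transition
width; the anchor values (tumour radius, host vascular fraction, peak IFP)
are the physical content, the profile shape is a modelling choice.

Saturations: the pore space (porosity ``eps``) is shared by tumour cells
(St), host cells (Sh) and interstitial fluid (Sl) with St+Sh+Sl=1; phase
volume fractions are eps*S. The vasculature occupies a separate fraction
``eps_v`` so that the solid (ECM) fraction is 1-eps-eps_v.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .grid import Grid2D, make_grid

__all__ = [
    "MMHG_TO_PA",
    "TissueState",
    "spherical_tumour_state",
    "ellipse_tumour_state",
    "clustered_np_field",
    "read_tissue_state_csv",
]

MMHG_TO_PA = 133.322

#: default plateau saturations; configurable in every generator
HOST_SATURATIONS = {"St": 0.0, "Sh": 0.6, "Sl": 0.4}
TUMOUR_SATURATIONS = {"St": 0.8, "Sh": 0.0, "Sl": 0.2}
DEFAULT_POROSITY = 0.8
DEFAULT_TRANSITION_MM = 0.05
#: effective Starling filtration pressure pv - pl (Pa); ~3 mmHg
DEFAULT_TRANSMURAL_PA = 400.0


@dataclass
class TissueState:
    """Nodal fields of a frozen tumour microenvironment."""

    grid: Grid2D
    eps: np.ndarray  # porosity (-)
    eps_v: np.ndarray  # vascular volume fraction (-)
    St: np.ndarray  # tumour-cell saturation (-)
    Sh: np.ndarray  # host-cell saturation (-)
    Sl: np.ndarray  # IF saturation (-)
    pl: np.ndarray  # IF pressure (Pa)
    pt: np.ndarray  # tumour-cell-phase pressure (Pa)
    pv: np.ndarray = field(default=None)  # homogenised blood pressure (Pa)

    def __post_init__(self):
        n = self.grid.n_nodes
        for name in ("eps", "eps_v", "St", "Sh", "Sl", "pl", "pt"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == ():
                arr = np.full(n, float(arr))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per node ({n})")
            setattr(self, name, arr)
        if self.pv is None:
            self.pv = self.pl + DEFAULT_TRANSMURAL_PA
        self.pv = np.broadcast_to(np.asarray(self.pv, dtype=float), (n,)).copy()

    def validate(self, atol: float = 1e-9) -> None:
        """Assert the saturation/volume-fraction invariants at every node."""
        sat = self.St + self.Sh + self.Sl
        if not np.allclose(sat, 1.0, atol=atol):
            raise ValueError("saturations must sum to 1 at every node")
        for name in ("St", "Sh", "Sl", "eps"):
            a = getattr(self, name)
            if (a < -atol).any() or (a > 1 + atol).any():
                raise ValueError(f"{name} outside [0, 1]")
        if (self.eps_v < -atol).any():
            raise ValueError("eps_v must be non-negative")
        if (self.eps + self.eps_v > 1 + atol).any():
            raise ValueError("eps + eps_v must not exceed 1 (solid fraction >= 0)")

    def phase_fraction(self, phase: str) -> np.ndarray:
        """Volume fraction eps_alpha = eps * S_alpha of a fluid phase."""
        return self.eps * getattr(self, "S" + phase)

    # -- I/O ------------------------------------------------------------
    COLUMNS = ("x", "y", "eps", "eps_v", "St", "Sh", "Sl", "pl", "pt", "pv")

    def to_csv(self, path) -> None:
        """Write one row per node: x, y and all state fields."""
        data = np.column_stack(
            [self.grid.nodes[:, 0], self.grid.nodes[:, 1], self.eps, self.eps_v,
             self.St, self.Sh, self.Sl, self.pl, self.pt, self.pv]
        )
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(self.COLUMNS)
            w.writerows(data.tolist())

    def to_vtk(self, path) -> None:
        from .io import write_vtk_structured

        write_vtk_structured(
            path, self.grid,
            {"eps": self.eps, "eps_v": self.eps_v, "St": self.St, "Sh": self.Sh,
             "Sl": self.Sl, "pl": self.pl, "pt": self.pt, "pv": self.pv},
        )


def read_tissue_state_csv(path) -> TissueState:
    """Load a TissueState written by :meth:`TissueState.to_csv`.

    The grid is reconstructed from the node coordinates, which must form a
    regular lattice.
    """
    rows = np.genfromtxt(path, delimiter=",", names=True)
    x = np.unique(np.round(rows["x"], 12))
    y = np.unique(np.round(rows["y"], 12))
    grid = make_grid(len(x) - 1, len(y) - 1, float(x[-1] - x[0]), float(y[-1] - y[0]))
    order = np.lexsort((rows["x"], rows["y"]))
    kw = {name: np.asarray(rows[name])[order] for name in TissueState.COLUMNS[2:]}
    return TissueState(grid=grid, **kw)


def _smoothstep_inside(r: np.ndarray, radius: float, width: float) -> np.ndarray:
    """~1 inside ``r < radius``, ~0 outside, tanh transition of scale ``width``."""
    if radius <= 0:
        return np.zeros_like(r)
    if width <= 0:
        return (r < radius).astype(float)
    return 0.5 * (1.0 - np.tanh((r - radius) / width))


def _saturation_fields(mask, tumour_sat, host_sat):
    St = host_sat["St"] + (tumour_sat["St"] - host_sat["St"]) * mask
    Sh = host_sat["Sh"] + (tumour_sat["Sh"] - host_sat["Sh"]) * mask
    Sl = 1.0 - St - Sh
    return St, Sh, Sl


def spherical_tumour_state(
    grid: Grid2D,
    r_tumour: float,
    centre: tuple[float, float],
    host_eps_v: float = 0.028,
    p_max: float = 4.0 * MMHG_TO_PA,
    transition: float = DEFAULT_TRANSITION_MM,
    porosity: float = DEFAULT_POROSITY,
    tumour_sat: dict | None = None,
    host_sat: dict | None = None,
    transmural_dp: float = DEFAULT_TRANSMURAL_PA,
    dp_cell: float = 0.0,
    core_fraction: float = 0.5,
) -> TissueState:
    """Radially symmetric tumour state around ``centre``.

    St steps from the host value to its tumour plateau across ``r_tumour``
    (transition width ``transition`` mm). The growing mass collapses the
    vasculature in its interior: eps_v decays monotonically from
    ``host_eps_v`` outside to 0 in the avascular core of radius
    ``core_fraction * r_tumour`` (the tumour rim stays perfused). pl
    decays monotonically (linearly in radius) from ``p_max`` at the
    centre to 0 within about one radius beyond the rim (or at the domain
    corner on small domains), driving an outward interstitial flow.
    pt = pl + dp_cell*St; pv = pl + transmural_dp.
    """
    tumour_sat = dict(TUMOUR_SATURATIONS, **(tumour_sat or {}))
    host_sat = dict(HOST_SATURATIONS, **(host_sat or {}))
    cx, cy = centre
    r = np.hypot(grid.nodes[:, 0] - cx, grid.nodes[:, 1] - cy)

    mask = _smoothstep_inside(r, r_tumour, transition)
    St, Sh, Sl = _saturation_fields(mask, tumour_sat, host_sat)
    if (Sl < 0).any() or (Sl > 1).any():
        raise ValueError("saturation profile leaves [0, 1]; adjust plateau values")
    if r_tumour > 0:
        r_core = core_fraction * r_tumour
        r_mid = 0.5 * (r_core + r_tumour)
        w_cv = max((r_tumour - r_core) / 4.0, 1e-9)
        eps_v = host_eps_v * (1.0 - _smoothstep_inside(r, r_mid, w_cv))
    else:
        eps_v = np.full(grid.n_nodes, host_eps_v)

    if r_tumour > 0:
        corners = np.array([[0, 0], [grid.Lx, 0], [0, grid.Ly],
                            [grid.Lx, grid.Ly]], float)
        r_far = np.max(np.hypot(corners[:, 0] - cx, corners[:, 1] - cy))
        # elevated IFP decays within about one tumour radius beyond the
        # rim; on small domains it reaches the boundary
        r_support = min(2.0 * r_tumour, r_far)
        pl = p_max * np.clip(1.0 - r / r_support, 0.0, None)
    else:
        pl = np.zeros_like(r)

    pt = pl + dp_cell * St
    state = TissueState(
        grid=grid, eps=np.full(grid.n_nodes, porosity), eps_v=eps_v,
        St=St, Sh=Sh, Sl=Sl, pl=pl, pt=pt, pv=pl + transmural_dp,
    )
    state.validate()
    return state


def ellipse_tumour_state(
    grid: Grid2D,
    a: float,
    b: float,
    centre: tuple[float, float],
    orientation: float = 0.0,
    transition: float = DEFAULT_TRANSITION_MM,
    porosity: float = DEFAULT_POROSITY,
    tumour_sat: dict | None = None,
    host_sat: dict | None = None,
) -> TissueState:
    """Elliptical tumour with inert pressures and no vasculature.

    Used by the prescribed-field (temperature-only) scenario: the tumour
    interior is tumour cells plus interstitial fluid (St=0.65, Sl=0.35 by
    default, reflecting the high fluid fraction of glioblastoma
    xenografts); pressures and eps_v are zero.
    """
    cx, cy = centre
    xr = grid.nodes[:, 0] - cx
    yr = grid.nodes[:, 1] - cy
    c, s = np.cos(orientation), np.sin(orientation)
    u = c * xr + s * yr
    v = -s * xr + c * yr
    # axis-aligned extents of the rotated ellipse
    ext_x = np.hypot(a * c, b * s)
    ext_y = np.hypot(a * s, b * c)
    if cx - ext_x < -1e-9 or cx + ext_x > grid.Lx + 1e-9 or cy - ext_y < -1e-9 or cy + ext_y > grid.Ly + 1e-9:
        raise ValueError("ellipse exceeds the domain")
    # signed distance proxy: elliptical radius scaled to the local semi-axis
    rho = np.hypot(u / a, v / b)
    theta = np.arctan2(v / b, u / a)
    r_local = np.hypot(a * np.cos(theta), b * np.sin(theta))  # boundary radius
    # signed-distance proxy (rho-1)*r_local, smoothed like the spherical mask
    if transition > 0:
        mask = 0.5 * (1.0 - np.tanh((rho - 1.0) * r_local / transition))
    else:
        mask = (rho < 1.0).astype(float)

    tumour_sat = dict({"St": 0.65, "Sh": 0.0, "Sl": 0.35}, **(tumour_sat or {}))
    host_sat = dict(HOST_SATURATIONS, **(host_sat or {}))
    St, Sh, Sl = _saturation_fields(mask, tumour_sat, host_sat)
    zero = np.zeros(grid.n_nodes)
    state = TissueState(
        grid=grid, eps=np.full(grid.n_nodes, porosity), eps_v=zero.copy(),
        St=St, Sh=Sh, Sl=Sl, pl=zero.copy(), pt=zero.copy(), pv=zero.copy(),
    )
    state.validate()
    return state


def tumour_mask(state: TissueState, threshold: float = 0.5) -> np.ndarray:
    """Boolean nodal mask of the tumour area (St above ``threshold``)."""
    return state.St > threshold


def clustered_np_field(
    grid: Grid2D,
    tumour_mask: np.ndarray,
    n_clusters: int,
    cluster_radius: float,
    base_field: np.ndarray,
    seed: int,
    state: TissueState | None = None,
) -> np.ndarray:
    """Redistribute a nanoparticle mass-fraction field into discs.

    Returns a field that vanishes outside ``n_clusters`` discs (within the
    tumour) and is elevated inside them such that the integrated
    nanoparticle mass rho_l*eps*Sl*omega over the tumour area equals that
    of ``base_field`` exactly (relative tolerance 1e-6 by construction).
    Deterministic for a given ``seed``. Cluster centres are drawn from the
    tumour nodes with a minimum-distance (dart-throwing) rule.
    """
    base_field = np.asarray(base_field, dtype=float)
    if (base_field < 0).any():
        raise ValueError("base_field must be non-negative")
    mask = np.asarray(tumour_mask, bool)
    if not mask.any():
        raise ValueError("tumour mask is empty")
    rng = np.random.default_rng(seed)
    pts = grid.nodes[mask]

    # weight by pore-fluid content so equal-mass matching is well defined
    if state is not None:
        w = (state.eps * state.Sl)[mask]
    else:
        w = np.ones(pts.shape[0])

    vol = grid.nodal_volumes()[mask]
    target = float(np.sum(base_field[mask] * w * vol))

    # place cluster centres inside the mask, well separated
    centres = []
    candidates = pts[vol > 0]
    for attempt in range(2000):
        c = candidates[rng.integers(len(candidates))]
        if all(np.hypot(*(c - o)) >= 1.8 * cluster_radius for o in centres):
            centres.append(c)
        if len(centres) == n_clusters:
            break
    else:
        raise ValueError(
            f"could not place {n_clusters} clusters of radius {cluster_radius} "
            f"inside the tumour mask after 2000 attempts"
        )

    in_cluster = np.zeros(grid.n_nodes, bool)
    for c in centres:
        r = np.hypot(grid.nodes[:, 0] - c[0], grid.nodes[:, 1] - c[1])
        in_cluster |= r <= cluster_radius
    in_cluster &= mask
    if not in_cluster.any():
        raise ValueError("clusters cover no tumour nodes; increase cluster_radius")

    field = np.zeros(grid.n_nodes)
    field[in_cluster] = 1.0
    wfull = np.zeros(grid.n_nodes)
    wfull[mask] = w
    current = float(np.sum(field * wfull * grid.nodal_volumes()))
    field *= target / current
    return field
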