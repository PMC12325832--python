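"""Discrete 1D microvasculature: synthetic trees, Hagen-Poiseuille flow,
1D nanoparticle advection-diffusion, and tumour-induced vessel collapse.

The vessel network is a graph of straight cylindrical segments with per-
segment radius. Blood flow obeys Hagen-Poiseuille resistance
Q = pi R^4 dp / (8 mu L) with pressure boundary conditions at the single
inlet (feeding arteriole) and at the terminal outlets. Nanoparticles in
the blood follow a 1D advection-diffusion equation on the graph with
upwinded advection, an inlet Dirichlet mass fraction, and a distributed
exchange sink that couples to the surrounding tissue.

Synthetic trees emulate the statistics of measured planar microvascular
networks: a radius range with a prescribed mean, one feeding vessel, and
Murray's law r_parent^gamma = sum r_child^gamma at bifurcations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "VesselNetwork",
    "generate_network",
    "collapse_vessels",
    "solve_network_flow",
    "step_np_vessel_1d",
    "DEFAULT_BLOOD_VISCOSITY",
    "DEFAULT_INLET_DP",
]

DEFAULT_BLOOD_VISCOSITY = 3.5e-3  # Pa s, standard literature value
DEFAULT_INLET_DP = 1000.0  # Pa head between the feeding arteriole and outlets


@dataclass
class VesselNetwork:
    """Graph of cylindrical vessel segments.

    nodes: (n, 2) junction coordinates in mm. segments: (m, 2) node-index
    pairs. radii: (m,) in mm. ``collapsed`` flags segments excluded from
    flow, transport, exchange and heat sinks.
    """

    nodes: np.ndarray
    segments: np.ndarray
    radii: np.ndarray
    inlet_nodes: np.ndarray
    outlet_nodes: np.ndarray
    inlet_pressure: float = DEFAULT_INLET_DP
    outlet_pressure: float = 0.0
    inlet_omega: float = 0.0
    collapsed: np.ndarray = None
    pressures: np.ndarray = None  # per node (Pa), set by solve_network_flow
    flows: np.ndarray = None  # per segment (mm^3/s), signed n0 -> n1
    omega: np.ndarray = None  # per node 1D NP mass fraction

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float).reshape(-1, 2)
        self.segments = np.asarray(self.segments, int).reshape(-1, 2)
        self.radii = np.asarray(self.radii, float).ravel()
        self.inlet_nodes = np.atleast_1d(np.asarray(self.inlet_nodes, int))
        self.outlet_nodes = np.atleast_1d(np.asarray(self.outlet_nodes, int))
        if self.collapsed is None:
            self.collapsed = np.zeros(len(self.segments), bool)
        self.collapsed = np.asarray(self.collapsed, bool).ravel()
        if (self.radii[~self.collapsed] <= 0).any():
            raise ValueError("uncollapsed segments must have positive radius")
        if self.omega is None:
            self.omega = np.zeros(len(self.nodes))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def lengths(self) -> np.ndarray:
        p0 = self.nodes[self.segments[:, 0]]
        p1 = self.nodes[self.segments[:, 1]]
        return np.hypot(*(p1 - p0).T)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.segments[:, 0]] + self.nodes[self.segments[:, 1]])

    def active(self) -> np.ndarray:
        return ~self.collapsed

    def total_length(self, active_only: bool = True) -> float:
        L = self.lengths
        return float(L[self.active()].sum() if active_only else L.sum())

    def mean_radius(self, active_only: bool = True) -> float:
        r = self.radii[self.active()] if active_only else self.radii
        return float(r.mean())

    def total_np_mass(self, rho_v: float = 1e-3) -> float:
        """Nanoparticle mass in the blood, sum over active segments of
        rho_v * pi R^2 * integral(omega) ds (trapezoidal per segment)."""
        act = self.active()
        seg = self.segments[act]
        om = 0.5 * (self.omega[seg[:, 0]] + self.omega[seg[:, 1]])
        return float(np.sum(rho_v * np.pi * self.radii[act] ** 2 * self.lengths[act] * om))

    # -- I/O ------------------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "nodes": self.nodes.tolist(),
            "segments": self.segments.tolist(),
            "radii": self.radii.tolist(),
            "inlet_nodes": self.inlet_nodes.tolist(),
            "outlet_nodes": self.outlet_nodes.tolist(),
            "inlet_pressure": self.inlet_pressure,
            "outlet_pressure": self.outlet_pressure,
            "collapsed": self.collapsed.astype(int).tolist(),
        }
        with open(path, "w") as f:
            json.dump(obj, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "VesselNetwork":
        with open(path) as f:
            obj = json.load(f)
        return cls(
            nodes=np.array(obj["nodes"]), segments=np.array(obj["segments"]),
            radii=np.array(obj["radii"]), inlet_nodes=np.array(obj["inlet_nodes"]),
            outlet_nodes=np.array(obj["outlet_nodes"]),
            inlet_pressure=obj.get("inlet_pressure", DEFAULT_INLET_DP),
            outlet_pressure=obj.get("outlet_pressure", 0.0),
            collapsed=np.array(obj.get("collapsed", []), bool)
            if obj.get("collapsed") else None,
        )

    def to_csv(self, path) -> None:
        """Edge list: n0, n1, x0, y0, x1, y1, radius_mm, collapsed."""
        import csv

        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["n0", "n1", "x0", "y0", "x1", "y1", "radius_mm", "collapsed"])
            for k, (a, b) in enumerate(self.segments):
                w.writerow([a, b, *self.nodes[a], *self.nodes[b],
                            self.radii[k], int(self.collapsed[k])])

    def to_vtk(self, path) -> None:
        from .io import write_vtk_polylines

        write_vtk_polylines(path, self.nodes, self.segments,
                            {"radius": self.radii, "collapsed": self.collapsed.astype(float),
                             "flow": np.zeros(self.n_segments) if self.flows is None else self.flows})


# ---------------------------------------------------------------------------
# Synthetic tree generation
# ---------------------------------------------------------------------------


def _build_tree(points: np.ndarray, root: np.ndarray, rng) -> tuple[list, list]:
    """Recursive binary clustering tree routing ``root`` to all points.

    Returns (node_coords, segments) with segments as index pairs into
    node_coords; node 0 is the root (inlet).
    """
    coords = [tuple(root)]
    segs = []

    def recurse(attach_idx: int, pts: np.ndarray):
        """Bifurcate at the attach point: one branch per point cluster."""
        if len(pts) == 1:
            p = pts[0]
            if np.hypot(*(p - coords[attach_idx])) < 1e-9:
                return
            coords.append(tuple(p))
            segs.append((attach_idx, len(coords) - 1))
            return
        # split along the principal axis of the point cloud
        mean = pts.mean(axis=0)
        d = pts - mean
        cov = d.T @ d
        _, vecs = np.linalg.eigh(cov)
        proj = d @ vecs[:, -1]
        med = np.median(proj)
        left = pts[proj <= med]
        right = pts[proj > med]
        if len(left) == 0 or len(right) == 0:  # degenerate split: halve by count
            order = np.argsort(proj)
            left, right = pts[order[: len(pts) // 2]], pts[order[len(pts) // 2:]]
        for cluster in (left, right):
            c = cluster.mean(axis=0)
            if len(cluster) == 1 or np.hypot(*(c - coords[attach_idx])) < 1e-9:
                recurse(attach_idx, cluster)
                continue
            coords.append(tuple(c))
            idx = len(coords) - 1
            segs.append((attach_idx, idx))
            recurse(idx, cluster)

    recurse(0, points)
    return coords, segs


def _murray_radii(n_nodes: int, segments: list, terminal_radius,
                  gamma: float) -> np.ndarray:
    """Per-segment radii: terminals get ``terminal_radius`` (scalar or
    per-segment array), parents obey Murray's law
    r_p^gamma = sum r_c^gamma."""
    children = {}
    for k, (a, b) in enumerate(segments):
        children.setdefault(a, []).append(k)
    parent_seg_of_node = {b: k for k, (a, b) in enumerate(segments)}
    radii = np.zeros(len(segments))

    def radius_of(k: int) -> float:
        if radii[k] > 0:
            return radii[k]
        _, b = segments[k]
        kids = children.get(b, [])
        if not kids:
            radii[k] = (terminal_radius if np.isscalar(terminal_radius)
                        else terminal_radius[k])
        else:
            radii[k] = sum(radius_of(c) ** gamma for c in kids) ** (1.0 / gamma)
        return radii[k]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(segments) + 1000))
    try:
        roots = [k for k, (a, b) in enumerate(segments) if a not in parent_seg_of_node]
        for k in roots:
            radius_of(k)
        for k in range(len(segments)):
            radius_of(k)
    finally:
        sys.setrecursionlimit(old)
    return radii


def generate_network(
    domain: tuple[float, float, float, float],
    target_mean_radius: float = 6.98e-3,
    radius_range: tuple[float, float] = (1.6e-3, 30e-3),
    n_terminal: int = 150,
    murray_exponent: float = 3.0,
    seed: int = 0,
    inlet_point: tuple[float, float] | None = None,
    margin: float = 0.02,
    max_retries: int = 25,
) -> VesselNetwork:
    """Synthesise a connected vessel tree with prescribed radius statistics.

    ``domain`` is (x0, y0, x1, y1) in mm. The tree is rooted at a single
    inlet on the left boundary, terminals are uniform random points, the
    topology is a recursive binary clustering tree, and radii follow
    Murray's law upward from a common terminal radius which is iterated so
    the empirical mean radius lands within 10% of ``target_mean_radius``
    (radii are clipped to ``radius_range``; Murray's law is exact wherever
    no clipping triggers). Deterministic for a given seed.
    """
    rmin, rmax = radius_range
    if not (rmin < target_mean_radius < rmax):
        raise ValueError("radius_range must bracket target_mean_radius")
    if n_terminal < 2:
        raise ValueError("need at least 2 terminals")
    x0, y0, x1, y1 = domain
    rng = np.random.default_rng(seed)
    if inlet_point is None:
        inlet_point = (x0, 0.5 * (y0 + y1))

    mx = margin * (x1 - x0)
    my = margin * (y1 - y0)
    pts = np.column_stack([
        rng.uniform(x0 + mx, x1 - mx, n_terminal),
        rng.uniform(y0 + my, y1 - my, n_terminal),
    ])
    coords, segs = _build_tree(pts, np.asarray(inlet_point, float), rng)
    nodes = np.asarray(coords)
    segments = np.asarray(segs, int)

    # terminal radius iteration toward the target mean; per-terminal
    # jitter spreads the capillary radii over the physiological range
    jitter = rng.uniform(0.55, 1.45, len(segments))
    r_t = target_mean_radius / 1.35  # binary-tree Murray mean ~ 1.35 r_t
    for _ in range(max_retries):
        radii = _murray_radii(len(nodes), segs, r_t * jitter, murray_exponent)
        radii = np.clip(radii, rmin, rmax)
        mean = radii.mean()
        if abs(mean - target_mean_radius) <= 0.10 * target_mean_radius:
            break
        r_t *= target_mean_radius / mean
        r_t = min(max(r_t, rmin), rmax)
    else:
        raise RuntimeError(
            f"could not reach mean radius {target_mean_radius:g} within 10% "
            f"after {max_retries} retries (last mean {mean:g})"
        )

    leaves = [b for _, b in segments if b not in segments[:, 0]]
    outlets = np.asarray(sorted(set(leaves)), int)
    return VesselNetwork(
        nodes=nodes, segments=segments, radii=radii,
        inlet_nodes=np.array([0]), outlet_nodes=outlets,
    )


def calibrated_network(
    domain: tuple[float, float, float, float],
    target_length_density: float = 12.0,  # mm vessel per mm^2 plan-view area
    seed: int = 0,
    **kwargs,
) -> VesselNetwork:
    """Generate a tree whose plan-view length density matches a target.

    The terminal count controls the total length (roughly like sqrt(n));
    a couple of deterministic regeneration passes adjust it.
    """
    x0, y0, x1, y1 = domain
    area = (x1 - x0) * (y1 - y0)
    target_length = target_length_density * area
    n = kwargs.pop("n_terminal", 200)
    net = None
    for _ in range(8):
        net = generate_network(domain, n_terminal=n, seed=seed, **kwargs)
        L = net.total_length(active_only=False)
        if abs(L - target_length) <= 0.10 * target_length:
            return net
        n = max(4, int(round(n * (target_length / L) ** 2)))
        n = min(n, 20000)
    return net


# ---------------------------------------------------------------------------
# Collapse and flow
# ---------------------------------------------------------------------------


def _sample_nodal(grid, field: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a nodal grid field at arbitrary points."""
    x = np.clip(points[:, 0], 0, grid.Lx * (1 - 1e-15))
    y = np.clip(points[:, 1], 0, grid.Ly * (1 - 1e-15))
    ix = np.minimum((x / grid.hx).astype(int), grid.nx - 1)
    iy = np.minimum((y / grid.hy).astype(int), grid.ny - 1)
    xi = x / grid.hx - ix
    eta = y / grid.hy - iy
    nxp = grid.nx + 1
    f = np.asarray(field)
    n00 = iy * nxp + ix
    return ((1 - xi) * (1 - eta) * f[n00] + xi * (1 - eta) * f[n00 + 1]
            + xi * eta * f[n00 + nxp + 1] + (1 - xi) * eta * f[n00 + nxp])


def collapse_vessels(net: VesselNetwork, state, St_threshold: float = 0.5) -> VesselNetwork:
    """Flag segments inside the tumour (midpoint St above threshold) as
    collapsed, then prune everything no longer connected to the inlet."""
    St_mid = _sample_nodal(state.grid, state.St, net.midpoints)
    collapsed = net.collapsed | (St_mid > St_threshold)

    # connectivity pruning from the inlet over uncollapsed segments
    adj = {}
    for k, (a, b) in enumerate(net.segments):
        if collapsed[k]:
            continue
        adj.setdefault(a, []).append((b, k))
        adj.setdefault(b, []).append((a, k))
    reachable_segs = np.zeros(net.n_segments, bool)
    seen = set()
    stack = list(net.inlet_nodes)
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        for v, k in adj.get(u, []):
            reachable_segs[k] = True
            if v not in seen:
                stack.append(v)
    collapsed = collapsed | ~reachable_segs
    return replace_network(net, collapsed=collapsed)


def replace_network(net: VesselNetwork, **changes) -> VesselNetwork:
    fields = dict(
        nodes=net.nodes, segments=net.segments, radii=net.radii,
        inlet_nodes=net.inlet_nodes, outlet_nodes=net.outlet_nodes,
        inlet_pressure=net.inlet_pressure, outlet_pressure=net.outlet_pressure,
        inlet_omega=net.inlet_omega, collapsed=net.collapsed,
        pressures=net.pressures, flows=net.flows, omega=net.omega,
    )
    fields.update(changes)
    return VesselNetwork(**fields)


def solve_network_flow(net: VesselNetwork, mu_blood: float = DEFAULT_BLOOD_VISCOSITY) -> VesselNetwork:
    """Nodal pressures and segment flows from Hagen-Poiseuille conductances.

    Segment conductance g = pi R^4 / (8 mu L); flow (node0 -> node1
    positive) Q = g (p0 - p1). Signed flows balance at every interior
    junction by construction of the discrete Laplacian system.
    """
    act = net.active()
    segs = net.segments[act]
    L = net.lengths[act]
    g = np.pi * net.radii[act] ** 4 / (8.0 * mu_blood * L)

    n = net.n_nodes
    rows = np.concatenate([segs[:, 0], segs[:, 1], segs[:, 0], segs[:, 1]])
    cols = np.concatenate([segs[:, 0], segs[:, 1], segs[:, 1], segs[:, 0]])
    vals = np.concatenate([g, g, -g, -g])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tolil()

    fixed = {int(i): net.inlet_pressure for i in net.inlet_nodes}
    fixed.update({int(i): net.outlet_pressure for i in net.outlet_nodes})
    b = np.zeros(n)
    for i, p in fixed.items():
        A.rows[i] = [i]
        A.data[i] = [1.0]
        b[i] = p
    A = A.tocsc()

    # nodes with no active segment: pin to outlet pressure (inert)
    deg = np.zeros(n)
    np.add.at(deg, segs.ravel(), 1.0)
    orphan = (deg == 0) & ~np.isin(np.arange(n), list(fixed))
    if orphan.any():
        A = A.tolil()
        for i in np.flatnonzero(orphan):
            A.rows[i] = [int(i)]
            A.data[i] = [1.0]
            b[i] = net.outlet_pressure
        A = A.tocsc()

    # detect connected components without any pressure BC (singular system)
    p = spla.spsolve(A, b)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("singular flow system: an active subnetwork has no pressure BC")

    flows = np.zeros(net.n_segments)
    flows[act] = g * (p[segs[:, 0]] - p[segs[:, 1]])
    return replace_network(net, pressures=p, flows=flows)


def junction_imbalance(net: VesselNetwork) -> float:
    """Max |net signed flow| over interior junctions (conservation check)."""
    act = net.active()
    segs = net.segments[act]
    q = net.flows[act]
    bal = np.zeros(net.n_nodes)
    np.subtract.at(bal, segs[:, 0], q)
    np.add.at(bal, segs[:, 1], q)
    boundary = set(net.inlet_nodes) | set(net.outlet_nodes)
    deg = np.zeros(net.n_nodes)
    np.add.at(deg, segs.ravel(), 1)
    interior = [i for i in range(net.n_nodes) if deg[i] > 0 and i not in boundary]
    return float(np.max(np.abs(bal[interior]))) if interior else 0.0


# ---------------------------------------------------------------------------
# 1D refined transport mesh
# ---------------------------------------------------------------------------


@dataclass
class VesselMesh1D:
    """Segments subdivided so no 1D element exceeds ``h_max``.

    Carries the mapping back to parent segments so radii/flows are
    inherited, plus the per-node lumped blood volume used as the storage
    coefficient of the 1D transport equation.
    """

    net: VesselNetwork
    points: np.ndarray  # (n1d, 2) 1D node coordinates
    elems: np.ndarray  # (m1d, 2) 1D node pairs, oriented parent n0->n1
    parent_segment: np.ndarray  # (m1d,) index into net.segments
    node_of_net_node: dict

    @property
    def radii(self) -> np.ndarray:
        return self.net.radii[self.parent_segment]

    @property
    def flows(self) -> np.ndarray:
        return self.net.flows[self.parent_segment]

    @property
    def lengths(self) -> np.ndarray:
        p0 = self.points[self.elems[:, 0]]
        p1 = self.points[self.elems[:, 1]]
        return np.hypot(*(p1 - p0).T)


def build_vessel_mesh(net: VesselNetwork, h_max: float) -> VesselMesh1D:
    """Subdivide active segments into elements of length <= h_max."""
    pts = []
    node_map = {}

    def add_point(p) -> int:
        pts.append(p)
        return len(pts) - 1

    for i in range(net.n_nodes):
        node_map[i] = add_point(net.nodes[i])

    elems = []
    parent = []
    for k in np.flatnonzero(net.active()):
        a, b = net.segments[k]
        p0, p1 = net.nodes[a], net.nodes[b]
        L = np.hypot(*(p1 - p0))
        nsub = max(1, int(np.ceil(L / h_max)))
        prev = node_map[a]
        for s in range(1, nsub + 1):
            if s == nsub:
                nxt = node_map[b]
            else:
                nxt = add_point(p0 + (p1 - p0) * s / nsub)
            elems.append((prev, nxt))
            parent.append(k)
            prev = nxt
    return VesselMesh1D(
        net=net, points=np.asarray(pts), elems=np.asarray(elems, int),
        parent_segment=np.asarray(parent, int), node_of_net_node=node_map,
    )


class VesselTransport1D:
    """Backward-Euler 1D nanoparticle transport on a vessel mesh.

    Storage rho_v pi R^2 per length, upwind advection by the signed
    segment flow, Fickian diffusion D_1d, inlet Dirichlet mass fraction,
    free outflow at outlets. An exchange sink (g/(mm s), per 1D element)
    removes mass toward the tissue; its ledger total is returned by
    :meth:`step` so tissue and vessel books always match.
    """

    def __init__(self, mesh: VesselMesh1D, dt: float, D_1d: float, rho_v: float = 1e-3):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.mesh = mesh
        self.dt = dt
        self.rho_v = rho_v
        self._D = D_1d
        net = mesh.net
        n = len(mesh.points)
        m = len(mesh.elems)
        L = mesh.lengths
        R = mesh.radii
        A_cs = np.pi * R ** 2
        q = mesh.flows

        vol = np.zeros(n)
        np.add.at(vol, mesh.elems[:, 0], 0.5 * rho_v * A_cs * L)
        np.add.at(vol, mesh.elems[:, 1], 0.5 * rho_v * A_cs * L)
        self.storage = vol  # g per unit omega at each 1D node

        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        # diffusion (two-point flux) and upwind advection per element
        adv_out = np.zeros(n)  # advective flow leaving each node
        adv_in = np.zeros(n)  # advective flow entering each node
        for e in range(m):
            a, b = mesh.elems[e]
            gd = rho_v * A_cs[e] * D_1d / L[e]
            add(a, a, gd), add(b, b, gd), add(a, b, -gd), add(b, a, -gd)
            Qm = rho_v * q[e]  # mass flow rate per unit omega, oriented a->b
            if Qm >= 0:
                add(a, a, Qm)   # leaves a
                add(b, a, -Qm)  # enters b
                adv_out[a] += Qm
                adv_in[b] += Qm
            else:
                add(b, b, -Qm)
                add(a, b, Qm)
                adv_out[b] += -Qm
                adv_in[a] += -Qm
        # nodes where more blood arrives than leaves through the network
        # (the terminal outlets) discharge it: the carried mass exits with
        # the local concentration
        discharge = np.clip(adv_in - adv_out, 0.0, None)
        for i in np.flatnonzero(discharge):
            add(int(i), int(i), discharge[i])
        self.discharge = discharge

        K = sp.coo_matrix((np.array(vals), (np.array(rows), np.array(cols))),
                          shape=(n, n)).tocsr()
        self.K = K

        self.inlet_1d = np.array([mesh.node_of_net_node[int(i)] for i in net.inlet_nodes])
        Asys = sp.diags(self.storage / dt) + K
        Asys = Asys.tolil()
        for i in self.inlet_1d:
            Asys.rows[i] = [int(i)]
            Asys.data[i] = [1.0]
        # isolated 1D nodes (from collapsed original junctions): identity
        iso = np.flatnonzero(self.storage == 0)
        for i in iso:
            if i not in self.inlet_1d:
                Asys.rows[i] = [int(i)]
                Asys.data[i] = [1.0]
        self.isolated = iso
        from .fem import LinearSolver

        self.solver = LinearSolver(Asys.tocsc())

        # precompute element lists touching inlet/outlet nodes for the ledger
        inlet_set = set(int(i) for i in self.inlet_1d)
        out_1d = set(mesh.node_of_net_node[int(i)] for i in net.outlet_nodes) - inlet_set
        self._inlet_elems = [(e, int(a), int(b)) for e, (a, b) in enumerate(mesh.elems)
                             if int(a) in inlet_set or int(b) in inlet_set]
        self._outlet_elems = [(e, int(a), int(b)) for e, (a, b) in enumerate(mesh.elems)
                              if int(a) in out_1d or int(b) in out_1d]
        self._inlet_set = inlet_set
        self._out_1d = out_1d

    def step(self, omega: np.ndarray, inlet_omega: float,
             sink_per_length: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
        """Advance one backward-Euler step.

        ``sink_per_length``: mass-exchange rate density (g/(mm s)) per 1D
        element, positive = mass leaving the vessel toward the tissue.
        Returns (new omega, ledger dict with inlet/outlet/exchange mass
        increments in g for this step).
        """
        mesh = self.mesh
        n = len(mesh.points)
        b = self.storage / self.dt * omega
        sink_nodes = np.zeros(n)
        if sink_per_length is not None:
            sL = np.asarray(sink_per_length) * mesh.lengths
            np.add.at(sink_nodes, mesh.elems[:, 0], 0.5 * sL)
            np.add.at(sink_nodes, mesh.elems[:, 1], 0.5 * sL)
            b -= sink_nodes
        for i in self.inlet_1d:
            b[i] = inlet_omega
        for i in self.isolated:
            if i not in self.inlet_1d:
                b[i] = omega[i]
        new = self.solver.solve(b)

        # mass ledger, evaluated implicitly (at the new iterate) so it
        # closes against the backward-Euler update exactly:
        # free-node mass change = inlet flux - outlet flux - exchange
        mesh = self.mesh
        dm = float(np.sum(self.storage * (new - omega)))
        dm_inlet = float(np.sum(self.storage[self.inlet_1d] *
                                (new[self.inlet_1d] - omega[self.inlet_1d])))
        exchange = float(np.sum(sink_nodes)) * self.dt
        exch_inlet = float(np.sum(sink_nodes[self.inlet_1d])) * self.dt

        L = mesh.lengths
        A_cs = np.pi * mesh.radii ** 2
        q = mesh.flows
        inlet_in = 0.0
        for e, a, b in self._inlet_elems:
            for node, other, sgn in ((a, b, 1.0), (b, a, -1.0)):
                if node in self._inlet_set:
                    Qm = self.rho_v * q[e] * sgn  # flow node -> other
                    adv = Qm * (new[node] if Qm >= 0 else new[other])
                    dif = self.rho_v * A_cs[e] * self._D / L[e] * (new[node] - new[other])
                    inlet_in += (adv + dif) * self.dt
        outlet_out = float(np.sum(self.discharge * new)) * self.dt
        ledger = {
            "d_mass": dm,
            "d_mass_free": dm - dm_inlet,
            "exchange": exchange - exch_inlet,
            "inlet_in": inlet_in,
            "outlet_out": outlet_out,
        }
        return new, ledger


def step_np_vessel_1d(net: VesselNetwork, dt: float, inlet_omega: float,
                      D_1d: float, exchange_sink: np.ndarray | None = None,
                      h_1d: float | None = None, rho_v: float = 1e-3) -> VesselNetwork:
    """One 1D transport step directly on the network graph (no subdivision
    beyond ``h_1d``); convenience wrapper used by tests and simple runs.

    ``exchange_sink``: per-network-node mass-exchange rate (g/s), positive
    removing mass. Returns a network with updated per-node omega.
    """
    if net.flows is None:
        raise ValueError("solve_network_flow must run before 1D transport")
    if h_1d is None:
        h_1d = max(net.lengths.max(), 1e-6)
    mesh = build_vessel_mesh(net, h_1d)
    stepper = VesselTransport1D(mesh, dt, D_1d, rho_v=rho_v)
    om = np.zeros(len(mesh.points))
    for i in range(net.n_nodes):
        om[mesh.node_of_net_node[i]] = net.omega[i]
    sink_per_len = None
    if exchange_sink is not None:
        # distribute a nodal (g/s) sink as a uniform density along the
        # parent segments incident to each network node
        per_node = np.asarray(exchange_sink, float)
        L = net.lengths
        act = net.active()
        seg_share = np.zeros(net.n_segments)
        for k in np.flatnonzero(act):
            a, b = net.segments[k]
            seg_share[k] = 0.5 * (per_node[a] + per_node[b])
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(L > 0, seg_share / L, 0.0)
        sink_per_len = dens[mesh.parent_segment]
    new_om, _ = stepper.step(om, inlet_omega, sink_per_len)
    if new_om.min() < -1e-12:
        raise RuntimeError("1D transport produced negative mass fraction")
    out = net.omega.copy()
    for i in range(net.n_nodes):
        out[i] = new_om[mesh.node_of_net_node[i]]
    return replace_network(net, omega=out)
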