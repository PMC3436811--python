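"""Cell geometry, cubic-lattice discretisation and crowding.

The reaction compartment is a spherical cell with an optional concentric
spherical nucleus.  The cell's bounding box is divided into ``L`` cubic
subvolumes per axis; cubes overlapping the cytoplasm become active
subvolumes whose volumes and mutual interface areas are clipped to the
cytoplasm by subsampling.  Diffusion between neighboring subvolumes is a
first-order jump with rate

    k(nu -> mu) = D * S_numu * phi_edge / (V_nu * phi_nu * l)

which reduces to ``D / l**2`` for interior, uncrowded cubes.  Crowding
enters through per-voxel free-volume fractions ``phi``; for homogeneous
(sub-voxel) crowding the ``phi`` factors cancel and diffusion is unchanged,
while voxel-scale obstacles produce a binary network and tortuous, slower
long-range transport.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _kernels

log = logging.getLogger(__name__)

#: Face directions: +x, -x, +y, -y, +z, -z.
DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64
)

#: Subvolumes with a clipped volume below this fraction of l^3 are merged
#: into their largest neighbor to avoid near-zero-volume propensity blowups.
SLIVER_FRACTION = 1e-6


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class CellGeometry:
    """Spherical cell with a concentric spherical nucleus (diameter 0 = none)."""

    cell_diameter: float
    nucleus_diameter: float = 0.0
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0 <= self.nucleus_diameter < self.cell_diameter:
            raise GeometryError("need 0 <= nucleus_diameter < cell_diameter")

    @property
    def cell_radius(self) -> float:
        return self.cell_diameter / 2.0

    @property
    def nucleus_radius(self) -> float:
        return self.nucleus_diameter / 2.0

    @property
    def cytoplasm_volume(self) -> float:
        """Analytic cytoplasm volume (cell minus nucleus), um^3."""
        return 4.0 / 3.0 * math.pi * (self.cell_radius**3 - self.nucleus_radius**3)

    @property
    def nucleus_area(self) -> float:
        return 4.0 * math.pi * self.nucleus_radius**2

    @property
    def membrane_area(self) -> float:
        return 4.0 * math.pi * self.cell_radius**2

    def nuclear_import_rate(self, permeability: float) -> float:
        """Volumetric first-order import rate k_s * A_nuc / V_cyt, s^-1.

        This is the well-mixed equivalent of a surface permeability: the
        nuclear envelope at 'concentration' A/V in the cytoplasm absorbs
        molecules at this aggregate rate.
        """
        if self.nucleus_diameter <= 0:
            return 0.0
        return permeability * self.nucleus_area / self.cytoplasm_volume


@dataclass
class ObstacleMap:
    """Per-voxel free-volume fractions phi in [0, 1]; phi = 0 is inaccessible."""

    phi: np.ndarray

    @classmethod
    def uniform(cls, shape, phi: float) -> "ObstacleMap":
        if not 0 < phi <= 1:
            raise GeometryError("uniform phi must lie in (0, 1]")
        return cls(np.full(shape, float(phi)))

    def free_fraction(self, mask=None) -> float:
        """Mean free-volume fraction, optionally over an active-voxel mask."""
        if mask is None:
            return float(self.phi.mean())
        return float(self.phi[mask].mean())


@dataclass
class SubvolumeView:
    """Read-only view of one lattice subvolume."""

    index: tuple
    vid: int
    V: float
    phi: float
    region: str
    neighbors: list  # (neighbor index triple, interface area, edge phi)
    nucleus_area: float
    membrane_area: float


class Lattice:
    """Cubic discretisation of a cell into ``U`` active subvolumes.

    Active subvolumes are numbered 0..U-1; dense per-volume arrays hold
    clipped volumes ``V``, free fractions ``phi``, per-face interface areas
    ``S``, edge free fractions ``edge_phi`` and neighbor ids (-1 = closed
    face).  ``vol_id`` maps a lattice index triple to the volume id.
    """

    def __init__(self, geom, L, l, x0, vol_id, ijk, V, phi, S, edge_phi, neighbor,
                 snuc, smem, region_grid, periodic=False, merged=0, spherical=False):
        self.geom = geom
        self.L = L
        self.l = l
        self.x0 = np.asarray(x0, dtype=float)
        self.vol_id = vol_id
        self.ijk = ijk
        self.V = V
        self.phi = phi
        self.S = S
        self.edge_phi = edge_phi
        self.neighbor = neighbor
        self.snuc = snuc
        self.smem = smem
        self.region_grid = region_grid
        self.periodic = periodic
        self.merged = merged
        #: True for clipped spherical-cell lattices; False for box lattices
        self.spherical = spherical

    @property
    def n_volumes(self) -> int:
        return len(self.V)

    U = n_volumes

    @property
    def centers(self) -> np.ndarray:
        return self.x0 + (self.ijk + 0.5) * self.l

    @property
    def free_volume(self) -> np.ndarray:
        return self.V * self.phi

    def total_volume(self) -> float:
        return float(self.V.sum())

    def locate(self, points) -> np.ndarray:
        """Volume id containing each point (-1 if outside the active lattice)."""
        pts = np.atleast_2d(points)
        idx = np.floor((pts - self.x0) / self.l).astype(np.int64)
        shape = np.array(self.vol_id.shape)
        if self.periodic:
            idx %= shape
            ok = np.ones(len(pts), dtype=bool)
        else:
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.full(len(pts), -1, dtype=np.int64)
        out[ok] = self.vol_id[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        return out

    def subvolume(self, index) -> SubvolumeView:
        if isinstance(index, (int, np.integer)):
            vid = int(index)
        else:
            vid = int(self.vol_id[tuple(index)])
        if vid < 0:
            i, j, k = index
            reg = {0: "outside", 1: "cytoplasm", 2: "nucleus"}[int(self.region_grid[i, j, k])]
            return SubvolumeView(tuple(index), -1, 0.0, 0.0, reg, [], 0.0, 0.0)
        nbrs = [
            (tuple(self.ijk[self.neighbor[vid, d]]), self.S[vid, d], self.edge_phi[vid, d])
            for d in range(6)
            if self.neighbor[vid, d] >= 0
        ]
        return SubvolumeView(
            tuple(self.ijk[vid]), vid, float(self.V[vid]), float(self.phi[vid]),
            "cytoplasm", nbrs, float(self.snuc[vid]), float(self.smem[vid]),
        )

    # -- diffusion ----------------------------------------------------------

    def jump_rate(self, D: float, u, v) -> float:
        """Diffusion jump rate constant from subvolume ``u`` to neighbor ``v``.

        ``k = D * S * phi_edge / (V_u * phi_u * l)``; returns 0 for a closed
        face and for an inaccessible (phi = 0) source.
        """
        uu = u if isinstance(u, (int, np.integer)) else self.vol_id[tuple(u)]
        vv = v if isinstance(v, (int, np.integer)) else self.vol_id[tuple(v)]
        if uu < 0 or vv < 0:
            return 0.0
        if self.phi[uu] <= 0:
            return 0.0
        for d in range(6):
            if self.neighbor[uu, d] == vv:
                return float(
                    D * self.S[uu, d] * self.edge_phi[uu, d]
                    / (self.V[uu] * self.phi[uu] * self.l)
                )
        raise GeometryError(f"subvolumes {u} and {v} are not adjacent")

    def jump_factors(self) -> np.ndarray:
        """(U, 6) geometric jump factors g such that k = D * g per face."""
        g = np.zeros_like(self.S)
        src_ok = self.phi > 0
        denom = np.where(src_ok, self.V * self.phi * self.l, 1.0)
        g[src_ok] = (self.S * self.edge_phi)[src_ok] / denom[src_ok, None]
        return g

    def jump_displacements(self) -> np.ndarray:
        """(U, 6, 3) physical displacement of each jump, um."""
        return np.broadcast_to(DIRS[None, :, :] * self.l, (self.n_volumes, 6, 3)).astype(float)


# -- construction -------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _surface_area_per_cube(center, radius, x0, l, L, n_points=100_000):
    """Apportion a sphere's surface area to the lattice cubes it crosses."""
    area = np.zeros((L, L, L))
    if radius <= 0:
        return area
    pts = center + radius * _fibonacci_sphere(n_points)
    idx = np.floor((pts - x0) / l).astype(np.int64)
    np.clip(idx, 0, L - 1, out=idx)
    np.add.at(area, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return area * (4.0 * math.pi * radius**2 / n_points)


def _edge_phi(phi_a, phi_b):
    """Free fraction of the shared face between voxels with node fractions a, b.

    Zero if either voxel is inaccessible, else the mean: exact in both limit
    cases (homogeneous sub-voxel crowding and binary voxel-scale obstacles).
    """
    if phi_a <= 0 or phi_b <= 0:
        return 0.0
    return 0.5 * (phi_a + phi_b)


def discretize_cell(geom: CellGeometry, L: int, obstacles: ObstacleMap | None = None,
                    subsamples: int = 10) -> Lattice:
    """Partition the cell's bounding box into an ``L^3`` cubic lattice.

    A cube is an active subvolume iff its clipped cytoplasm overlap volume is
    positive (and its free fraction, if an obstacle map is given, is > 0).
    Boundary cubes get subsampled volumes (``subsamples**3`` points) and
    interface areas (``subsamples**2`` points per face); sliver cubes below
    ``SLIVER_FRACTION * l**3`` are merged into their largest neighbor.
    """
    if L < 1:
        raise GeometryError("L must be >= 1")
    R, Rn = geom.cell_radius, geom.nucleus_radius
    center = np.asarray(geom.center, dtype=float)
    l = geom.cell_diameter / L
    x0 = center - R
    # coarse lattices have few, large boundary cubes: refine their sampling
    s = max(int(subsamples), int(math.ceil(4 * subsamples / L)))

    lo_x = x0[0] + l * np.arange(L)
    lo_y = x0[1] + l * np.arange(L)
    lo_z = x0[2] + l * np.arange(L)
    mins = np.stack(np.meshgrid(lo_x, lo_y, lo_z, indexing="ij"), -1)
    c = mins + l / 2.0
    rel = np.abs(c - center)
    near = np.sqrt((np.maximum(rel - l / 2.0, 0.0) ** 2).sum(-1))
    far = np.sqrt(((rel + l / 2.0) ** 2).sum(-1))

    frac = np.zeros((L, L, L))
    interior = (far <= R) & ((Rn == 0) | (near >= Rn))
    frac[interior] = 1.0
    outside = near >= R
    in_nucleus = far <= Rn
    boundary = ~interior & ~outside & ~in_nucleus
    bidx = np.argwhere(boundary)
    if len(bidx):
        off = (np.stack(np.meshgrid(*[np.arange(s)] * 3, indexing="ij"), -1).reshape(-1, 3)
               + 0.5) * (l / s)
        pts = mins[bidx[:, 0], bidx[:, 1], bidx[:, 2]][:, None, :] + off[None, :, :]
        d = np.linalg.norm(pts - center, axis=-1)
        frac[bidx[:, 0], bidx[:, 1], bidx[:, 2]] = ((d <= R) & (d >= Rn)).mean(axis=1)

    region_grid = np.zeros((L, L, L), dtype=np.int8)
    region_grid[frac > 0] = 1
    region_grid[in_nucleus | ((frac == 0) & ~outside & ~interior & (near < Rn))] = 2
    region_grid[in_nucleus] = 2

    phi_grid = np.ones((L, L, L)) if obstacles is None else np.asarray(obstacles.phi, dtype=float)
    if phi_grid.shape != (L, L, L):
        raise GeometryError("obstacle map shape must match the lattice")
    active = (frac > 0) & (phi_grid > 0)

    # merge sliver cubes into their largest active neighbor
    V_grid = frac * l**3
    merged = 0
    sliver = active & (V_grid < SLIVER_FRACTION * l**3)
    for i, j, k in np.argwhere(sliver):
        best, best_v = None, 0.0
        for d in DIRS:
            ii, jj, kk = i + d[0], j + d[1], k + d[2]
            if 0 <= ii < L and 0 <= jj < L and 0 <= kk < L and active[ii, jj, kk] \
                    and not sliver[ii, jj, kk] and V_grid[ii, jj, kk] > best_v:
                best, best_v = (ii, jj, kk), V_grid[ii, jj, kk]
        if best is not None:
            V_grid[best] += V_grid[i, j, k]
        active[i, j, k] = False
        merged += 1
    if merged:
        log.info("merged %d sliver subvolumes into neighbors", merged)

    ijk = np.argwhere(active)
    U = len(ijk)
    vol_id = np.full((L, L, L), -1, dtype=np.int64)
    vol_id[active] = np.arange(U)
    V = V_grid[active]
    phi = phi_grid[active]

    neighbor = np.full((U, 6), -1, dtype=np.int64)
    S = np.zeros((U, 6))
    edge_phi = np.zeros((U, 6))
    interior_act = interior[active]

    # face areas along each positive axis, mirrored to the negative slot
    foff = (np.arange(s) + 0.5) * (l / s)
    f2 = np.stack(np.meshgrid(foff, foff, indexing="ij"), -1).reshape(-1, 2)
    for axis in range(3):
        d_pos, d_neg = 2 * axis, 2 * axis + 1
        a = ijk
        b = a + DIRS[d_pos]
        ok = b[:, axis] < L
        u_ids = np.arange(U)[ok]
        bb = b[ok]
        v_ids = vol_id[bb[:, 0], bb[:, 1], bb[:, 2]]
        pair_ok = v_ids >= 0
        u_ids, v_ids = u_ids[pair_ok], v_ids[pair_ok]
        both_interior = interior_act[u_ids] & interior_act[v_ids]
        areas = np.zeros(len(u_ids))
        areas[both_interior] = l * l
        need = ~both_interior
        if need.any():
            ui = u_ids[need]
            plane = x0[axis] + (ijk[ui, axis] + 1) * l
            other = [ax for ax in range(3) if ax != axis]
            pts = np.empty((len(ui), s * s, 3))
            pts[:, :, axis] = plane[:, None]
            base = x0[other[0]] + ijk[ui, other[0]] * l
            pts[:, :, other[0]] = base[:, None] + f2[None, :, 0]
            base = x0[other[1]] + ijk[ui, other[1]] * l
            pts[:, :, other[1]] = base[:, None] + f2[None, :, 1]
            dd = np.linalg.norm(pts - center, axis=-1)
            areas[need] = ((dd <= R) & (dd >= Rn)).mean(axis=1) * l * l
        has_face = areas > 0
        uu, vv, aa = u_ids[has_face], v_ids[has_face], areas[has_face]
        neighbor[uu, d_pos] = vv
        neighbor[vv, d_neg] = uu
        S[uu, d_pos] = aa
        S[vv, d_neg] = aa
        ep = np.array([_edge_phi(phi[x], phi[y]) for x, y in zip(uu, vv)])
        edge_phi[uu, d_pos] = ep
        edge_phi[vv, d_neg] = ep

    snuc_grid = _surface_area_per_cube(center, Rn, x0, l, L)
    smem_grid = _surface_area_per_cube(center, R, x0, l, L)
    snuc = snuc_grid[active]
    smem = smem_grid[active]

    return Lattice(geom, L, l, x0, vol_id, ijk, V, phi, S, edge_phi, neighbor,
                   snuc, smem, region_grid, periodic=False, merged=merged, spherical=True)


def box_lattice(shape, l: float, obstacles: ObstacleMap | None = None,
                periodic: bool = True) -> Lattice:
    """Uniform cubic box lattice (no cell clipping), optionally periodic.

    Used for free-diffusion checks and crowding studies where membrane
    curvature is irrelevant.
    """
    shape = tuple(int(n) for n in (shape if np.iterable(shape) else (shape,) * 3))
    nx_, ny_, nz_ = shape
    phi_grid = np.ones(shape) if obstacles is None else np.asarray(obstacles.phi, dtype=float)
    if phi_grid.shape != shape:
        raise GeometryError("obstacle map shape must match the lattice")
    active = phi_grid > 0
    ijk = np.argwhere(active)
    U = len(ijk)
    vol_id = np.full(shape, -1, dtype=np.int64)
    vol_id[active] = np.arange(U)
    V = np.full(U, l**3)
    phi = phi_grid[active]
    neighbor = np.full((U, 6), -1, dtype=np.int64)
    S = np.zeros((U, 6))
    edge_phi = np.zeros((U, 6))
    dims = np.array(shape)
    for d in range(6):
        nb = ijk + DIRS[d]
        if periodic:
            nb = nb % dims
            ok = np.ones(U, dtype=bool)
        else:
            ok = np.all((nb >= 0) & (nb < dims), axis=1)
        vids = np.full(U, -1, dtype=np.int64)
        vids[ok] = vol_id[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
        good = vids >= 0
        neighbor[good, d] = vids[good]
        S[good, d] = l * l
        edge_phi[good, d] = [
            _edge_phi(phi[u], phi[v]) for u, v in zip(np.arange(U)[good], vids[good])
        ]
    geom = CellGeometry(cell_diameter=float(max(shape) * l))
    region_grid = np.where(active, 1, 0).astype(np.int8)
    return Lattice(geom, max(shape), l, np.zeros(3), vol_id, ijk, V, phi, S, edge_phi,
                   neighbor, np.zeros(U), np.zeros(U), region_grid, periodic=periodic)


# -- obstacle generation ------------------------------------------------------


def generate_obstacle_map(lattice: Lattice, target_phi: float, blob_radius: float,
                          seed: int, tol: float = 0.01, max_attempts: int = 100_000) -> ObstacleMap:
    """Random impenetrable spherical blobs until the free fraction hits a target.

    Synthetic stand-in for microscopy-derived obstacle geometries: spheres of
    ``blob_radius`` are dropped uniformly over the lattice; voxels whose
    center falls inside a blob become inaccessible (phi = 0).  Blobs that
    would overshoot below ``target_phi - tol`` are rejected, so the map
    converges whenever one blob's voxel footprint is small enough.
    Deterministic given ``seed``.
    """
    if not 0 < target_phi <= 1:
        raise GeometryError("target_phi must lie in (0, 1]")
    shape = lattice.vol_id.shape
    phi = np.ones(shape)
    if target_phi >= 1.0:
        return ObstacleMap(phi)
    rng = np.random.default_rng(seed)
    active = lattice.vol_id >= 0
    centers = lattice.x0 + (np.indices(shape).transpose(1, 2, 3, 0) + 0.5) * lattice.l
    total = int(active.sum())
    free = total
    box = np.array(shape) * lattice.l
    attempts = 0
    while free / total > target_phi + tol:
        if attempts >= max_attempts:
            raise GeometryError(
                f"could not reach phi={target_phi} with blob radius {blob_radius}"
            )
        attempts += 1
        cb = lattice.x0 + rng.random(3) * box
        dist = np.linalg.norm(centers - cb, axis=-1)
        hit = (dist < blob_radius) & active & (phi > 0)
        n_hit = int(hit.sum())
        if n_hit == 0:
            continue
        if (free - n_hit) / total < target_phi - tol:
            continue  # this blob would overshoot; try another position
        phi[hit] = 0.0
        free -= n_hit
    return ObstacleMap(phi)


# -- diffusion network --------------------------------------------------------


def build_diffusion_network(lattice: Lattice, diffusion: float = 1.0) -> nx.DiGraph:
    """Directed graph of the lattice diffusion system.

    Node weight is the local free-volume fraction; each open face yields two
    directed edges whose ``rate`` is the jump rate constant for a species
    with diffusion coefficient ``diffusion`` (rates differ between the two
    directions when the node fractions differ).
    """
    g = nx.DiGraph()
    for u in range(lattice.n_volumes):
        g.add_node(u, phi=float(lattice.phi[u]), ijk=tuple(lattice.ijk[u]))
    gfac = lattice.jump_factors()
    for u in range(lattice.n_volumes):
        for d in range(6):
            v = lattice.neighbor[u, d]
            if v >= 0 and gfac[u, d] > 0:
                g.add_edge(u, int(v), rate=float(diffusion * gfac[u, d]),
                           edge_phi=float(lattice.edge_phi[u, d]))
    n_comp = nx.number_weakly_connected_components(g) if g.number_of_nodes() else 0
    if n_comp > 1:
        log.info("diffusion network has %d disconnected components", n_comp)
    return g


# -- effective diffusion ------------------------------------------------------


def estimate_effective_diffusion(times, positions, d_ref: float) -> float:
    """Ratio D_eff / D_ref from walker trajectories.

    ``positions`` is (T, n, 3) displacement-from-start (um) at the matching
    ``times``; the mean-square displacement is fit through the origin as
    ``MSD = 6 D_eff t``.
    """
    times = np.asarray(times, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[0] != len(times):
        raise GeometryError("positions must be (T, n, 3) matching times")
    n = pos.shape[1]
    if n < 100 or len(times) < 2:
        raise GeometryError(
            f"insufficient samples for a diffusion fit: need >= 100 walkers and"
            f" >= 2 recording times, got {n} and {len(times)}"
        )
    msd = (pos**2).sum(axis=2).mean(axis=1)
    slope = float((msd * times).sum() / (times**2).sum())
    return slope / (6.0 * d_ref)


def run_lattice_tracers(lattice: Lattice, diffusion: float, n_walkers: int,
                        rec_times, seed: int, start_vols=None):
    """Population-level pure diffusion: independent tracers jumping on the lattice.

    Returns ``(rec_times, positions, volumes)`` with positions as unwrapped
    displacements suitable for :func:`estimate_effective_diffusion`.
    """
    rec_times = np.asarray(rec_times, dtype=float)
    gfac = lattice.jump_factors() * diffusion
    cum = np.cumsum(gfac, axis=1)
    total = cum[:, -1].copy()
    rng = np.random.default_rng(seed)
    if start_vols is None:
        start_vols = rng.integers(0, lattice.n_volumes, n_walkers)
    start_vols = np.asarray(start_vols, dtype=np.int64)
    kseed = int(rng.integers(0, 2**31 - 1))
    pos, vol = _kernels.tracer_kmc(
        total, cum, lattice.neighbor, lattice.jump_displacements(), start_vols,
        rec_times, kseed,
    )
    return rec_times, pos, vol


def run_box_walkers(lattice: Lattice, diffusion: float, n_walkers: int, dt: float,
                    rec_times, seed: int):
    """Particle-level pure diffusion in a periodic box lattice with obstacles."""
    if not lattice.periodic:
        raise GeometryError("run_box_walkers needs a periodic box lattice")
    rec_times = np.asarray(rec_times, dtype=float)
    shape = lattice.vol_id.shape
    blocked = (lattice.vol_id < 0).astype(np.uint8)
    box = np.array(shape, dtype=float) * lattice.l
    rng = np.random.default_rng(seed)
    # start walkers uniformly over free voxels
    free = np.argwhere(blocked == 0)
    pick = free[rng.integers(0, len(free), n_walkers)]
    start = (pick + rng.random((n_walkers, 3))) * lattice.l
    n_frames = len(rec_times)
    n_steps = int(round(rec_times[-1] / dt))
    rec_every = max(1, n_steps // n_frames)
    kseed = int(rng.integers(0, 2**31 - 1))
    traj = _kernels.brownian_box(start, diffusion, dt, rec_every * n_frames,
                                 rec_every, box, blocked, lattice.l, kseed)
    times = dt * rec_every * (1 + np.arange(n_frames))
    return times, traj


# -- placement ---------------------------------------------------------------


def uniform_on_sphere(n: int, radius: float, rng, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """n points uniformly distributed on a sphere surface."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v


def uniform_in_cytoplasm(lattice: Lattice, n: int, rng, species_radius: float = 0.0,
                         max_iter: int = 1000) -> np.ndarray:
    """n points uniform over the accessible cytoplasm (rejection sampling).

    Rejects points outside the cell shell, inside the nucleus, or in
    inaccessible voxels.
    """
    geom = lattice.geom
    R = geom.cell_radius - species_radius
    Rn = geom.nucleus_radius
    center = np.asarray(geom.center, dtype=float)
    box = np.array(lattice.vol_id.shape) * lattice.l
    out = np.empty((n, 3))
    got = 0
    for _ in range(max_iter):
        m = max(2 * (n - got), 64)
        if lattice.spherical:
            pts = center + (rng.random((m, 3)) - 0.5) * 2 * R
            r = np.linalg.norm(pts - center, axis=1)
            pts = pts[(r < R) & (r > Rn)]
        else:
            pts = lattice.x0 + rng.random((m, 3)) * box
        if len(pts):
            ok2 = lattice.locate(pts) >= 0
            pts = pts[ok2]
        take = min(len(pts), n - got)
        out[got:got + take] = pts[:take]
        got += take
        if got == n:
            return out
    raise GeometryError("rejection sampling failed: accessible cytoplasm too small?")


def uniform_in_subvolume(lattice: Lattice, v: int, n: int, rng,
                         species_radius: float = 0.0, max_iter: int = 2000) -> np.ndarray:
    """n points uniform over the cytoplasm part of subvolume ``v``.

    ``species_radius`` keeps molecule centers a molecular radius off the
    plasma membrane; for fully interior cubes this is plain uniform
    sampling over the cube.
    """
    geom = lattice.geom
    R, Rn = geom.cell_radius - species_radius, geom.nucleus_radius
    center = np.asarray(geom.center, dtype=float)
    corner = lattice.x0 + lattice.ijk[v] * lattice.l
    out = np.empty((n, 3))
    got = 0
    for _ in range(max_iter):
        m = max(2 * (n - got), 32)
        pts = corner + rng.random((m, 3)) * lattice.l
        if lattice.spherical:
            r = np.linalg.norm(pts - center, axis=1)
            pts = pts[(r < R) & (r > Rn)]
        take = min(len(pts), n - got)
        out[got:got + take] = pts[:take]
        got += take
        if got == n:
            return out
    raise GeometryError(f"could not place points in subvolume {v}")
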