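"""Off-lattice Brownian-dynamics particle engine.

Each tracked molecule carries a position and its own next first-order
reaction time, drawn from the species' aggregate first-order rate when the
molecule is created.  Diffusion is an explicit-timestep random walk
``x' = x + sqrt(2 D dt) xi``; steps into forbidden space (outside the cell,
into the nucleus, into obstacle voxels) are rejected, i.e. the particle
keeps its position for that step.  Crossing attempts at the nuclear
envelope or plasma membrane become absorption events with probability
``k_s sqrt(pi dt / D)`` for a surface permeability ``k_s`` (um/s).
Bimolecular reactions are collision-driven: pairs closer than the summed
radii may react with probability ``k_sim dt / V_sigma``.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from . import _kernels
from .model import ReactionNetwork, bimolecular_rate_to_volume_rate

log = logging.getLogger(__name__)
INF = math.inf


def brownian_step(position, diffusion: float, dt: float, rng):
    """Propose Brownian displacement(s): x + sqrt(2 D dt) * xi, xi ~ N(0, I3)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    position = np.asarray(position, dtype=float)
    return position + math.sqrt(2.0 * diffusion * dt) * rng.standard_normal(position.shape)


def surface_transfer_probability(k_s: float, dt: float, diffusion: float) -> float:
    """Per-crossing-attempt absorption probability for a permeability k_s.

    The um/s permeability of a partially absorbing surface translates into
    a per-attempt probability ``k_s sqrt(pi dt / D)`` for a random walker
    with step size sqrt(2 D dt); clipped at 1 with a warning (dt too large).
    """
    if k_s <= 0:
        return 0.0
    if diffusion <= 0:
        return 0.0
    p = k_s * math.sqrt(math.pi * dt / diffusion)
    if p > 1.0:
        log.warning("surface transfer probability %.3g > 1 clipped; reduce dt", p)
        return 1.0
    return p


def bimolecular_probability(k: float, sigma: float, dt: float) -> float:
    """Per-step reaction probability for a colliding pair.

    ``P = k_sim dt / V_sigma`` with ``k_sim`` the pair volume rate (um^3/s)
    and ``V_sigma`` the collision sphere ``(4/3) pi sigma^3``: the pair is
    treated as well mixed within its collision volume.  Clipped at 1 with a
    warning that dt should be reduced.
    """
    if k <= 0:
        return 0.0
    if sigma <= 0:
        raise ValueError("collision radius must be positive for a bimolecular channel")
    v_sigma = 4.0 / 3.0 * math.pi * sigma**3
    p = bimolecular_rate_to_volume_rate(k) * dt / v_sigma
    if p > 1.0:
        log.warning("bimolecular reaction probability %.3g > 1 clipped; reduce dt", p)
        return 1.0
    return p


def schedule_first_order(k1_aggregate: float, now: float, rng) -> float:
    """Next first-order reaction time of a newly created molecule."""
    if k1_aggregate <= 0:
        return INF
    return now + rng.exponential(1.0 / k1_aggregate)


class ParticleEngine:
    """Store and propagator for individually tracked molecules.

    Particles live in flat arrays (position, species, own next first-order
    time, monotone id); removal marks ``alive`` False and the store is
    compacted periodically.  The engine does not decide reactions across
    levels -- it reports boundary events (nuclear import, membrane
    adsorption, walks into population-mode volumes) to the caller.
    """

    def __init__(self, network: ReactionNetwork, lattice):
        self.network = network
        self.lattice = lattice
        m = network.n_species
        self.pos = np.zeros((0, 3))
        self.species = np.zeros(0, dtype=np.int64)
        self.t_next = np.zeros(0)
        self.ids = np.zeros(0, dtype=np.int64)
        self.alive = np.zeros(0, dtype=bool)
        self._next_id = 0
        #: absorbed molecules: row 0 nucleus pool, row 1 membrane pool
        self.pools = np.zeros((2, m), dtype=np.int64)

        geom = lattice.geom
        self.r_nuc = geom.nucleus_radius
        self.r_cell_eff = geom.cell_radius - network.radius
        # surface channels per species
        self.ks_import = np.zeros(m)
        self.ks_adsorb = np.zeros(m)
        self.prod_import = np.arange(m, dtype=np.int64)
        self.prod_adsorb = np.arange(m, dtype=np.int64)
        for r in network.surface_transfers:
            i = network.index[r.reactants[0]]
            prod = network.index[r.products[0]] if r.products else i
            if r.surface == "nucleus":
                self.ks_import[i] = r.rate_constant
                self.prod_import[i] = prod
            else:
                self.ks_adsorb[i] = r.rate_constant
                self.prod_adsorb[i] = prod
        self.reactive = np.array([(network.sigma[i] >= 0).any() for i in range(m)])
        self.sigma2 = np.where(network.sigma >= 0, network.sigma**2, -1.0)
        self._pair_buf = (np.zeros(256, dtype=np.int64), np.zeros(256, dtype=np.int64))

    # -- store management ---------------------------------------------------

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def _grow(self, extra):
        n = len(self.ids)
        self.pos = np.vstack([self.pos, np.zeros((extra, 3))])
        self.species = np.concatenate([self.species, np.zeros(extra, dtype=np.int64)])
        self.t_next = np.concatenate([self.t_next, np.zeros(extra)])
        self.ids = np.concatenate([self.ids, np.zeros(extra, dtype=np.int64)])
        self.alive = np.concatenate([self.alive, np.zeros(extra, dtype=bool)])
        return n

    def add_particles(self, species, positions, now: float = 0.0, rng=None,
                      t_next=None) -> np.ndarray:
        """Create particles; fresh first-order schedules unless given."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        k = len(positions)
        i = species if isinstance(species, (int, np.integer)) \
            else self.network.index[species]
        start = self._grow(k)
        sl = slice(start, start + k)
        self.pos[sl] = positions
        self.species[sl] = i
        self.ids[sl] = self._next_id + np.arange(k)
        self._next_id += k
        self.alive[sl] = True
        if t_next is not None:
            self.t_next[sl] = t_next
        else:
            k1 = self.network.k1_aggregate[i]
            if k1 > 0:
                if rng is None:
                    raise ValueError("rng required to schedule first-order times")
                self.t_next[sl] = now + rng.exponential(1.0 / k1, size=k)
            else:
                self.t_next[sl] = INF
        return np.arange(start, start + k)

    def remove(self, idx) -> None:
        self.alive[idx] = False

    def compact(self) -> None:
        keep = self.alive
        self.pos = self.pos[keep]
        self.species = self.species[keep]
        self.t_next = self.t_next[keep]
        self.ids = self.ids[keep]
        self.alive = self.alive[keep]

    def census(self) -> np.ndarray:
        """(U, M) particle counts per (subvolume, species)."""
        out = np.zeros((self.lattice.n_volumes, self.network.n_species), dtype=np.int64)
        live = np.flatnonzero(self.alive)
        if len(live):
            vols = self.lattice.locate(self.pos[live])
            if (vols < 0).any():
                raise RuntimeError("live particle outside the active lattice")
            np.add.at(out, (vols, self.species[live]), 1)
        return out

    def particles_in_volume(self, v: int, species: int | None = None) -> np.ndarray:
        live = np.flatnonzero(self.alive)
        if not len(live):
            return live
        vols = self.lattice.locate(self.pos[live])
        sel = vols == v
        if species is not None:
            sel &= self.species[live] == species
        return live[sel]

    # -- dynamics -----------------------------------------------------------

    def step(self, dt: float, rng, mode=None):
        """One Brownian step for every live particle.

        Returns ``(imported, adsorbed, handover)``: indices of particles
        absorbed through the nucleus, bound to the membrane, and a list of
        ``(index, volume)`` for particles that walked into population-mode
        subvolumes.  Pools are updated here; handover particles are already
        removed from the store and must be inserted into the population
        state by the caller.
        """
        n = len(self.ids)
        if n == 0:
            return np.zeros(0, np.int64), np.zeros(0, np.int64), []
        d = self.network.diffusion
        cache = getattr(self, "_step_cache", None)
        if cache is None or cache[0] != dt:
            sd_step = np.sqrt(2.0 * d * dt)
            p_import = np.array([
                surface_transfer_probability(self.ks_import[i], dt, d[i]) for i in range(len(d))
            ])
            p_adsorb = np.array([
                surface_transfer_probability(self.ks_adsorb[i], dt, d[i]) for i in range(len(d))
            ])
            # level-interface acceptance: permeability D/l (the lattice
            # exchange velocity) converted to a per-crossing probability
            p_handover = np.array([
                surface_transfer_probability(d[i] / self.lattice.l, dt, d[i])
                for i in range(len(d))
            ])
            self._step_cache = cache = (dt, sd_step, p_import, p_adsorb, p_handover)
        _, sd_step, p_import, p_adsorb, p_handover = cache
        normals = rng.standard_normal((n, 3))
        uniforms = rng.random(n)
        codes = np.zeros(n, dtype=np.int64)
        target = np.zeros(n, dtype=np.int64)
        if mode is None:
            mode = np.zeros((self.lattice.n_volumes, self.network.n_species), dtype=np.uint8)
        box = np.array(self.lattice.vol_id.shape, dtype=float) * self.lattice.l
        _kernels.step_particles_cell(
            self.pos, self.species, self.alive, normals, uniforms,
            sd_step, self.r_cell_eff, self.r_nuc, p_import, p_adsorb, p_handover,
            self.lattice.x0, self.lattice.l, self.lattice.vol_id, mode,
            codes, target, self.lattice.spherical, self.lattice.periodic, box,
        )
        if (codes == _kernels.STEP_CORRUPT).any():
            raise RuntimeError("particle in illegal position: state corrupted")
        imported = np.flatnonzero(codes == _kernels.STEP_IMPORTED)
        for j in imported:
            self.pools[0, self.prod_import[self.species[j]]] += 1
        adsorbed = np.flatnonzero(codes == _kernels.STEP_ADSORBED)
        for j in adsorbed:
            self.pools[1, self.prod_adsorb[self.species[j]]] += 1
        hand = np.flatnonzero(codes == _kernels.STEP_TO_POPULATION)
        handover = [(int(j), int(target[j])) for j in hand]
        return imported, adsorbed, handover

    def detect_collisions(self) -> np.ndarray:
        """Candidate reactive pairs (k, 2), each once, ordered by ids."""
        sig = self.network.sigma
        max_sigma = sig.max() if sig.size else -1.0
        if max_sigma <= 0 or self.n_alive < 2:
            return np.zeros((0, 2), dtype=np.int64)
        h = max(max_sigma, 1e-6)
        origin = self.lattice.x0 - h
        extent = self.lattice.vol_id.shape[0] * self.lattice.l + 2 * h
        dims = np.full(3, int(math.ceil(extent / h)) + 2, dtype=np.int64)
        while True:
            out_a, out_b = self._pair_buf
            cnt = _kernels.detect_pairs(
                self.pos, self.species, self.alive, self.ids, self.reactive,
                self.sigma2, h, origin, dims, out_a, out_b,
            )
            if cnt <= len(out_a):
                break
            self._pair_buf = (np.zeros(2 * cnt, dtype=np.int64),
                              np.zeros(2 * cnt, dtype=np.int64))
        pairs = np.stack([out_a[:cnt], out_b[:cnt]], axis=1)
        # deterministic processing order: ascending (id_a, id_b)
        order = np.lexsort((self.ids[pairs[:, 1]], self.ids[pairs[:, 0]]))
        return pairs[order]

    def first_order_due(self, t_sync: float) -> np.ndarray:
        """Live particles with t_next <= t_sync, ascending in time."""
        due = np.flatnonzero(self.alive & (self.t_next <= t_sync))
        return due[np.argsort(self.t_next[due], kind="stable")]
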