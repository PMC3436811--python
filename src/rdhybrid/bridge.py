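"""Cross-level machinery between the particle and population engines.

Every molecule lives at exactly one level, decided per (subvolume, species)
by the mode map.  Conversions and boundary crossings preserve first-order
waiting-time statistics without re-randomisation:

- particle -> population: counts come from the particle census and the
  species' stored time is the minimum of the converted particles' own times;
- population -> particle: N particles are placed uniformly; one inherits
  the stored species time t, the others get t + Exp(k1) (their reaction
  must come after the first);
- a population-level diffusion jump into a particle-mode volume creates a
  particle carrying the stored time with probability 1/N;
- a particle walking into a population-mode volume min-merges its own time
  into the stored species time;
- a particle meeting a population-mode reaction partner reacts as a
  quasi-first-order channel with rate k_ij N_j / V per timestep.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .geometry import DIRS, uniform_in_subvolume
from .gillespie import GillespieEngine
from .particles import ParticleEngine

INF = math.inf


class ModeMap:
    """Per-(subvolume, species) level assignment.

    ``population[v, i]`` is 1 where species i is population-tracked in
    subvolume v and 0 where it is particle-tracked; the array is shared with
    the population engine, so controller edits apply immediately.
    """

    def __init__(self, lattice, network, population=None):
        self.lattice = lattice
        self.network = network
        U, M = lattice.n_volumes, network.n_species
        self.population = np.ones((U, M), dtype=np.uint8) if population is None \
            else np.asarray(population, dtype=np.uint8).reshape(U, M).copy()

    @classmethod
    def all_population(cls, lattice, network):
        return cls(lattice, network)

    @classmethod
    def all_particle(cls, lattice, network):
        m = cls(lattice, network)
        m.population[:] = 0
        return m

    @classmethod
    def per_species(cls, lattice, network, particle_species):
        """Whole-cell split: the named species are particle-mode everywhere."""
        m = cls(lattice, network)
        for name in particle_species:
            m.population[:, network.index[name]] = 0
        return m

    @classmethod
    def particle_near_surfaces(cls, lattice, network, species=None, width_factor: float = 1.0):
        """Particle mode in every subvolume within one lattice spacing of the
        plasma membrane or nuclear envelope, population mode elsewhere."""
        m = cls(lattice, network)
        geom = lattice.geom
        centers = lattice.centers
        rel = np.abs(centers - np.asarray(geom.center))
        near = np.sqrt((np.maximum(rel - lattice.l / 2, 0) ** 2).sum(1))
        far = np.sqrt(((rel + lattice.l / 2) ** 2).sum(1))
        width = width_factor * lattice.l

        def shell_dist(radius):
            inside = (near <= radius) & (far >= radius)
            d = np.where(inside, 0.0, np.minimum(np.abs(near - radius), np.abs(far - radius)))
            return d

        sel = shell_dist(geom.cell_radius) <= width
        if geom.nucleus_radius > 0:
            sel |= shell_dist(geom.nucleus_radius) <= width
        cols = range(network.n_species) if species is None else \
            [network.index[s] for s in species]
        for i in cols:
            m.population[sel, i] = 0
        return m

    def is_particle(self, v, i) -> bool:
        return self.population[v, i] == 0


class HybridBridge:
    """Executes all events that touch both levels.

    Owns no state of its own beyond audit counters; it mutates the two
    engines it couples.  All random draws use either the master numpy
    generator (particle placement, channel choice) or the compiled stream
    (carry decisions inside kernel helpers), both seeded from the run seed.
    """

    def __init__(self, network, lattice, population: GillespieEngine,
                 particles: ParticleEngine, mode: ModeMap, rng, dt: float):
        self.network = network
        self.lattice = lattice
        self.pop = population
        self.par = particles
        self.mode = mode
        self.rng = rng
        self.dt = dt
        population.mode = mode.population  # share the array
        self.audit = {
            "jumps_to_particles": 0, "particle_handover": 0,
            "conversions_to_population": 0, "conversions_to_particles": 0,
            "cross_level_reactions": 0, "bridged_reactions": 0,
        }

    # -- population events needing particle handling ------------------------

    def handle_population_event(self, event) -> None:
        t = event.time
        v = event.volume
        M = self.network.n_species
        if event.code == _kernels.ADV_JUMP_BRIDGE:
            self._jump_into_particle_volume(v, event.slot - M, event.aux, t)
        elif event.code == _kernels.ADV_FO_BRIDGE:
            self._fo_with_particle_products(v, event.slot, event.aux, t)
        elif event.code == _kernels.ADV_R2_BRIDGE:
            self._r2_with_particle_products(v, event.aux, t)
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unknown bridge event code {event.code}")

    def _jump_into_particle_volume(self, v: int, i: int, direction: int, t: float) -> None:
        """A population molecule jumps into a volume where i is particle-mode.

        The created particle inherits the stored species time with
        probability 1/N (the source then redraws from the remaining N-1),
        otherwise it gets the memoryless min + Exp(k1) draw.  No aggregated
        time is tracked in the target volume.
        """
        nb = int(self.lattice.neighbor[v, direction])
        t_next = _kernels.fo_remove_one(self.pop.counts, self.pop.times, v, i, t, self.pop.k1)
        self.pop.counts[v, i] -= 1
        pos = self._entry_slab_position(v, direction, nb, i)
        self.par.add_particles(i, pos[None, :], t_next=t_next)
        self.pop.refresh_volume(v, t, fired_slot=self.network.n_species + i)
        self.audit["jumps_to_particles"] += 1

    def _entry_slab_position(self, v: int, direction: int, nb: int, i: int) -> np.ndarray:
        """Uniform position in a thin slab of the target volume adjacent to
        the shared face; preserves flux directionality at the interface."""
        l = self.lattice.l
        depth = min(l / 10.0, math.sqrt(2.0 * max(self.network.diffusion[i], 1e-30) * self.dt))
        corner = self.lattice.x0 + self.lattice.ijk[nb] * l
        axis = direction // 2
        positive = direction % 2 == 0  # jump along +axis: enters nb at its low face
        for _ in range(64):
            p = corner + self.rng.random(3) * l
            off = self.rng.random() * depth
            p[axis] = corner[axis] + off if positive else corner[axis] + l - off
            if self._position_ok(p, i):
                return p
        return uniform_in_subvolume(self.lattice, nb, 1, self.rng,
                                    species_radius=self.network.radius[i])[0]

    def _position_ok(self, p, i) -> bool:
        geom = self.lattice.geom
        if self.lattice.spherical:
            r = float(np.linalg.norm(p - np.asarray(geom.center)))
            if r >= geom.cell_radius - self.network.radius[i] or r <= geom.nucleus_radius:
                return False
        return self.lattice.locate(p[None, :])[0] >= 0

    def _fo_with_particle_products(self, v: int, i: int, channel: int, t: float) -> None:
        """First-order population event whose products include particle-mode
        species: products in particle-mode slots become particles placed at
        a uniform position in the subvolume."""
        net = self.network
        _kernels.fo_fire_min(self.pop.counts, self.pop.times, v, i, t, self.pop.k1)
        delta = net.fo_delta[channel]
        pos = uniform_in_subvolume(self.lattice, v, 1, self.rng,
                                   species_radius=float(net.radius.max()))[0]
        for s2 in range(net.n_species):
            add = delta[s2] + (1 if s2 == i else 0)
            if self.mode.population[v, s2]:
                self.pop.counts[v, s2] += delta[s2]
                for _ in range(max(add, 0)):
                    _kernels.fo_add_one(self.pop.times, v, s2, t, self.pop.k1)
            else:
                for _ in range(max(add, 0)):
                    self.par.add_particles(s2, pos[None, :], now=t, rng=self.rng)
        self.pop.refresh_volume(v, t)
        self.audit["bridged_reactions"] += 1

    def _r2_with_particle_products(self, v: int, channel: int, t: float) -> None:
        net = self.network
        a, b = int(net.r2_a[channel]), int(net.r2_b[channel])
        _kernels.fo_remove_one(self.pop.counts, self.pop.times, v, a, t, self.pop.k1)
        self.pop.counts[v, a] -= 1
        _kernels.fo_remove_one(self.pop.counts, self.pop.times, v, b, t, self.pop.k1)
        self.pop.counts[v, b] -= 1
        delta = net.r2_delta[channel]
        pos = uniform_in_subvolume(self.lattice, v, 1, self.rng,
                                   species_radius=float(net.radius.max()))[0]
        for s2 in range(net.n_species):
            add = delta[s2] + (1 if s2 == a else 0) + (1 if s2 == b else 0)
            if add <= 0:
                continue
            if self.mode.population[v, s2]:
                self.pop.counts[v, s2] += add
                for _ in range(add):
                    _kernels.fo_add_one(self.pop.times, v, s2, t, self.pop.k1)
            else:
                for _ in range(add):
                    self.par.add_particles(s2, pos[None, :], now=t, rng=self.rng)
        self.pop.refresh_volume(v, t, fired_slot=2 * net.n_species + channel)
        self.audit["bridged_reactions"] += 1

    # -- particle -> population crossings -----------------------------------

    def particle_handover(self, idx: int, v: int, t: float) -> None:
        """A particle walked into a volume where its species is population-mode."""
        i = int(self.par.species[idx])
        self.pop.insert_one(v, i, t, t_next=float(self.par.t_next[idx]))
        self.par.remove(idx)
        self.audit["particle_handover"] += 1

    # -- conversions ---------------------------------------------------------

    def convert_to_population(self, v: int, species, t: float) -> None:
        """Delete the particles of the given species in v; the species'
        stored first-order time becomes the minimum of their own times, and
        all jump/higher-order times are freshly initialised (their stored
        propensity was zero, so the refresh draws fresh times)."""
        for name in species:
            i = name if isinstance(name, (int, np.integer)) else self.network.index[name]
            idxs = self.par.particles_in_volume(v, i)
            self.mode.population[v, i] = 1
            if len(idxs):
                self.pop.counts[v, i] += len(idxs)
                tmin = float(self.par.t_next[idxs].min())
                self.pop.times[v, i] = min(self.pop.times[v, i], tmin)
                self.par.remove(idxs)
        self.pop.refresh_volume(v, t)
        self.audit["conversions_to_population"] += 1

    def convert_to_particles(self, v: int, species, t: float) -> None:
        """Create N uniformly placed particles; the first inherits the stored
        species time, the rest get stored + Exp(k1).  Jump and higher-order
        slots for the species fall to zero propensity and go to infinity."""
        for name in species:
            i = name if isinstance(name, (int, np.integer)) else self.network.index[name]
            n = int(self.pop.counts[v, i])
            t_slot = float(self.pop.times[v, i])
            self.mode.population[v, i] = 0
            self.pop.counts[v, i] = 0
            self.pop.times[v, i] = INF
            if n == 0:
                continue
            positions = uniform_in_subvolume(self.lattice, v, n, self.rng,
                                             species_radius=self.network.radius[i])
            k1 = self.network.k1_aggregate[i]
            if k1 > 0:
                t_nexts = np.full(n, INF)
                t_nexts[0] = t_slot
                if n > 1:
                    t_nexts[1:] = t_slot + self.rng.exponential(1.0 / k1, size=n - 1)
            else:
                t_nexts = np.full(n, INF)
            self.par.add_particles(i, positions, t_next=t_nexts)
        self.pop.refresh_volume(v, t)
        self.audit["conversions_to_particles"] += 1

    # -- cross-level bimolecular reactions (quasi-first-order) ---------------

    def cross_level_attempts(self, t: float) -> int:
        """Per-timestep reaction attempts of particles against population
        partners: particle i in volume v reacts with probability
        1 - exp(-k_ij N_j^v / V_v * dt)."""
        net = self.network
        n_react = 0
        live = np.flatnonzero(self.par.alive)
        if not len(live):
            return 0
        present = np.bincount(self.par.species[live], minlength=net.n_species)
        pop_present = self.pop.counts.any(axis=0)
        if not any(
            (present[net.r2_a[c]] and pop_present[net.r2_b[c]])
            or (present[net.r2_b[c]] and pop_present[net.r2_a[c]])
            for c in range(net.n_bimolecular)
        ):
            return 0
        vols = self.lattice.locate(self.par.pos[live])
        for ch in range(net.n_bimolecular):
            a, b = int(net.r2_a[ch]), int(net.r2_b[ch])
            for part_sp, pop_sp in ((a, b), (b, a)) if a != b else ((a, a),):
                sel = np.flatnonzero(self.par.alive[live] & (self.par.species[live] == part_sp))
                if not len(sel):
                    continue
                vv = vols[sel]
                pop_here = self.mode.population[vv, pop_sp] == 1
                nj = self.pop.counts[vv, pop_sp]
                cand = pop_here & (nj > 0)
                if not cand.any():
                    continue
                rate = net.r2_kvol[ch] * nj[cand] / self.pop.vfree[vv[cand]]
                p = 1.0 - np.exp(-rate * self.dt)
                hits = self.rng.random(len(p)) < p
                for j_loc, v in zip(np.asarray(sel)[cand][hits], vv[cand][hits]):
                    idx = int(live[j_loc])
                    if not self.par.alive[idx] or self.pop.counts[v, pop_sp] <= 0:
                        continue
                    self._execute_cross_level(idx, int(v), ch, part_sp, pop_sp, t)
                    n_react += 1
        return n_react

    def _execute_cross_level(self, idx: int, v: int, ch: int, part_sp: int,
                             pop_sp: int, t: float) -> None:
        net = self.network
        pos = self.par.pos[idx].copy()
        self.pop.remove_one(v, pop_sp, t)
        self.par.remove(idx)
        delta = net.r2_delta[ch]
        for s2 in range(net.n_species):
            add = delta[s2] + (1 if s2 == part_sp else 0) + (1 if s2 == pop_sp else 0)
            for _ in range(max(add, 0)):
                if self.mode.population[v, s2]:
                    self.pop.insert_one(v, s2, t)
                else:
                    self.par.add_particles(s2, pos[None, :], now=t, rng=self.rng)
        self.audit["cross_level_reactions"] += 1

    # -- automated switching -------------------------------------------------

    def mode_controller(self, t: float, threshold: int, hysteresis: float = 2.0) -> int:
        """Switch (subvolume, species) slots between levels by local count.

        Population slots below ``threshold`` molecules become particle-mode;
        particle slots at or above ``hysteresis * threshold`` become
        population-mode.  The hysteresis gap prevents flapping.  Returns the
        number of switches performed.
        """
        if threshold <= 0:
            return 0
        census = self.par.census()
        switches = 0
        for v in range(self.lattice.n_volumes):
            for i in range(self.network.n_species):
                if self.mode.population[v, i]:
                    if self.pop.counts[v, i] < threshold:
                        self.convert_to_particles(v, [i], t)
                        switches += 1
                elif census[v, i] >= hysteresis * threshold:
                    self.convert_to_population(v, [i], t)
                    switches += 1
        return switches
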