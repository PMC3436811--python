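"""Hybrid simulation master loop.

One global timestep ``dt`` synchronises the two levels.  Per step:

1. Brownian moves with boundary handling; particles crossing into
   population-mode volumes are handed over, surface crossings become
   absorption attempts;
2. collision-driven bimolecular attempts between particles, then
   quasi-first-order cross-level attempts against population partners;
3. per-particle first-order reactions due in this step, in time order;
4. the event-driven population engine advances to the synchronisation
   point (jumps into particle-mode volumes create particles);

then scheduled or controller-driven mode conversions are applied and
outputs are recorded.  The step order is fixed for reproducibility: a
fixed seed yields bit-identical trajectories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .bridge import HybridBridge, ModeMap
from .geometry import (CellGeometry, Lattice, discretize_cell, uniform_in_cytoplasm,
                       uniform_on_sphere)
from .gillespie import GillespieEngine
from .model import ReactionNetwork
from .particles import ParticleEngine, bimolecular_probability

log = logging.getLogger(__name__)
INF = math.inf


@dataclass
class SimulationConfig:
    """Run settings for the hybrid simulator.

    ``mode`` picks the level assignment: ``"population"``, ``"particle"``,
    ``("species", [names])`` (named species particle-mode everywhere) or
    ``("surfaces", [names or None])`` (particle mode within one lattice
    spacing of membrane and nucleus).  ``init`` lists
    ``(species, count, where)`` placements with ``where`` one of
    ``"membrane"``, ``"nucleus_surface"``, ``"cytoplasm"``.
    """

    cell_diameter: float = 10.0
    nucleus_diameter: float = 0.0
    grid_l: int = 10
    dt: float = 2.6e-5
    t_end: float = 1.0
    seed: int = 0
    mode: object = "population"
    init: list = field(default_factory=list)
    record_interval: float = 0.1
    controller_threshold: int = 0
    controller_interval: int = 100
    convert_every: int = 0        # full particle<->population flip cadence (tests)
    compact_every: int = 200
    n_radial_bins: int = 25
    obstacles: object = None
    snapshot_dir: str | None = None  # write particle CSV snapshots per record


@dataclass
class TrajectoryRecord:
    """Recorded time series of a hybrid run."""

    species: list
    times: np.ndarray
    population_totals: np.ndarray   # (T, M)
    particle_totals: np.ndarray     # (T, M)
    nucleus_pool: np.ndarray        # (T, M)
    membrane_pool: np.ndarray       # (T, M)
    radial_edges: np.ndarray
    radial_hist: np.ndarray         # (T, nbins, M)
    x_edges: np.ndarray
    x_hist: np.ndarray              # (T, nbins, M)
    audit: list                     # per-record dict of counters
    config: SimulationConfig | None = None

    def totals(self) -> np.ndarray:
        """(T, M) total copy numbers over levels and pools."""
        return (self.population_totals + self.particle_totals
                + self.nucleus_pool + self.membrane_pool)

    def species_index(self, name: str) -> int:
        return self.species.index(name)


class HybridSimulation:
    """Couples a particle engine and a population engine over one lattice."""

    def __init__(self, network: ReactionNetwork, lattice: Lattice, mode: ModeMap,
                 dt: float, seed: int):
        for r, status, k_d in network.check_diffusion_limits():
            if status == "diffusion_limited":
                log.warning(
                    "reaction %s + %s approaches the diffusion limit "
                    "(k=%.3g, k_D=%.3g M^-1 s^-1): population-level treatment "
                    "will underestimate the rate", r.reactants[0], r.reactants[1],
                    r.rate_constant, k_d)
        self.network = network
        self.lattice = lattice
        self.dt = dt
        self.rng = np.random.default_rng(seed)
        self.pop = GillespieEngine(network, lattice, mode.population)
        self.par = ParticleEngine(network, lattice)
        self.pop.pools = self.par.pools  # one shared pool accounting
        self.mode = mode
        self.bridge = HybridBridge(network, lattice, self.pop, self.par, mode,
                                   self.rng, dt)
        self.pop.seed(int(self.rng.integers(2**31 - 1)))
        self.t = 0.0
        self._initialized = False
        self.audit_particle_events = {"bimolecular": 0, "first_order": 0}
        # per-channel collision reaction probabilities (filled at run start)
        self._pair_prob = None

    # -- initial conditions -------------------------------------------------

    def place(self, species, n: int, where: str = "cytoplasm") -> None:
        """Place n molecules; the level follows the mode map at the position."""
        i = self.network.index[species] if isinstance(species, str) else int(species)
        geom = self.lattice.geom
        radius = self.network.radius[i]
        if where == "membrane":
            pos = uniform_on_sphere(n, geom.cell_radius - max(radius, 1e-3 * geom.cell_radius),
                                    self.rng, geom.center)
        elif where == "nucleus_surface":
            pos = uniform_on_sphere(n, geom.nucleus_radius + max(radius, 1e-3 * geom.cell_radius),
                                    self.rng, geom.center)
        elif where == "cytoplasm":
            pos = uniform_in_cytoplasm(self.lattice, n, self.rng, radius)
        else:
            raise ValueError(f"unknown placement {where!r}")
        vols = self.lattice.locate(pos)
        if (vols < 0).any():
            # membrane shell points can fall into clipped-away slivers; nudge inward
            bad = vols < 0
            pos[bad] *= 1.0 - self.lattice.l / (2 * geom.cell_radius)
            vols = self.lattice.locate(pos)
            if (vols < 0).any():
                raise RuntimeError("initial placement outside the active lattice")
        as_pop = self.mode.population[vols, i] == 1
        if as_pop.any():
            self.pop.add_molecules(i, vols[as_pop])
        if (~as_pop).any():
            self.par.add_particles(i, pos[~as_pop], now=0.0, rng=self.rng)

    def initialize(self) -> None:
        self.pop.initialize(0.0)
        self._pair_prob = np.array([
            bimolecular_probability(r.rate_constant,
                                    self.network.sigma[self.network.r2_a[c],
                                                       self.network.r2_b[c]],
                                    self.dt)
            if self.network.sigma[self.network.r2_a[c], self.network.r2_b[c]] > 0 else 0.0
            for c, r in enumerate(self.network.bimolecular)
        ])
        self._initialized = True

    # -- event execution on the particle level ------------------------------

    def _place_products(self, channel_delta, consumed, pos, t):
        """Create reaction products at ``pos``, level-resolved."""
        v = int(self.lattice.locate(pos[None, :])[0])
        for s2 in range(self.network.n_species):
            add = int(channel_delta[s2]) + consumed.count(s2)
            for _ in range(max(add, 0)):
                if self.mode.population[v, s2]:
                    self.pop.insert_one(v, s2, t)
                else:
                    self.par.add_particles(s2, pos[None, :], now=t, rng=self.rng)

    def _particle_bimolecular(self, t: float) -> None:
        # collision search only pays off when both reactants of some channel
        # actually have particles in play
        live = self.par.species[self.par.alive]
        if not len(live):
            return
        present = np.bincount(live, minlength=self.network.n_species)
        possible = False
        for c in range(self.network.n_bimolecular):
            a, b = self.network.r2_a[c], self.network.r2_b[c]
            if (present[a] >= 2 if a == b else present[a] >= 1 and present[b] >= 1):
                possible = True
                break
        if not possible:
            return
        pairs = self.par.detect_collisions()
        if not len(pairs):
            return
        u = self.rng.random(len(pairs))
        for (a, b), ua in zip(pairs, u):
            if not (self.par.alive[a] and self.par.alive[b]):
                continue  # consumed by an earlier pair this step
            ch = self.network.pair_channel[self.par.species[a], self.par.species[b]]
            if ch < 0 or ua >= self._pair_prob[ch]:
                continue
            sa, sb = int(self.par.species[a]), int(self.par.species[b])
            mid = 0.5 * (self.par.pos[a] + self.par.pos[b])
            self.par.remove([a, b])
            self._place_products(self.network.r2_delta[ch], [sa, sb], mid, t)
            self.audit_particle_events["bimolecular"] += 1

    def _particle_first_order(self, t_sync: float) -> None:
        due = self.par.first_order_due(t_sync)
        for idx in due:
            if not self.par.alive[idx]:
                continue
            i = int(self.par.species[idx])
            t_fire = float(self.par.t_next[idx])
            r = self.network.select_first_order_channel(i, self.rng)
            pos = self.par.pos[idx].copy()
            self.par.remove(idx)
            self._place_products(self.network.stoich_delta(r), [i], pos, t_fire)
            self.audit_particle_events["first_order"] += 1

    # -- main loop -----------------------------------------------------------

    def step(self, step_index: int) -> None:
        t_sync = (step_index + 1) * self.dt
        imported, adsorbed, handover = self.par.step(self.dt, self.rng,
                                                     self.mode.population)
        for idx, v in handover:
            self.bridge.particle_handover(idx, v, t_sync)
        self._particle_bimolecular(t_sync)
        self.bridge.cross_level_attempts(t_sync)
        self._particle_first_order(t_sync)
        self.pop.advance_until(t_sync, self.bridge.handle_population_event)
        self.t = t_sync

    def run(self, t_end: float, record_interval: float | None = None,
            controller_threshold: int = 0, controller_interval: int = 100,
            convert_every: int = 0, compact_every: int = 200,
            n_radial_bins: int = 25, snapshot_dir=None, config=None) -> TrajectoryRecord:
        if not self._initialized:
            self.initialize()
        n_steps = int(round(t_end / self.dt))
        if record_interval is None:
            record_interval = t_end if t_end > 0 else 1.0
        rec_every = max(1, int(round(record_interval / self.dt)))
        rec = _Recorder(self, n_radial_bins, snapshot_dir)
        rec.snapshot(0.0)
        # pure population runs need no per-dt synchronisation: advance the
        # event-driven engine record interval by record interval
        if (len(self.par.ids) == 0 and not convert_every and not controller_threshold
                and self.mode.population.all()):
            for s in range(rec_every - 1, n_steps, rec_every):
                t_sync = (s + 1) * self.dt
                self.pop.advance_until(t_sync, self.bridge.handle_population_event)
                self.t = t_sync
                rec.snapshot(self.t)
            if n_steps % rec_every:
                t_sync = n_steps * self.dt
                self.pop.advance_until(t_sync, self.bridge.handle_population_event)
                self.t = t_sync
                rec.snapshot(self.t)
            return rec.finish(config)
        for s in range(n_steps):
            self.step(s)
            if convert_every and (s + 1) % convert_every == 0:
                self._full_flip()
            if controller_threshold and (s + 1) % controller_interval == 0:
                self.bridge.mode_controller(self.t, controller_threshold)
            if (s + 1) % compact_every == 0:
                self.par.compact()
            if (s + 1) % rec_every == 0 or s == n_steps - 1:
                rec.snapshot(self.t)
        return rec.finish(config)

    def _full_flip(self) -> None:
        """Flip every (volume, species) slot to the other level (test hook)."""
        for v in range(self.lattice.n_volumes):
            to_particles = [i for i in range(self.network.n_species)
                            if self.mode.population[v, i]]
            to_population = [i for i in range(self.network.n_species)
                             if not self.mode.population[v, i]]
            if to_particles:
                self.bridge.convert_to_particles(v, to_particles, self.t)
            if to_population:
                self.bridge.convert_to_population(v, to_population, self.t)


class _Recorder:
    def __init__(self, sim: HybridSimulation, n_radial_bins: int, snapshot_dir=None):
        self.sim = sim
        self.snapshot_dir = snapshot_dir
        self._snap_index = 0
        geom = sim.lattice.geom
        self.redges = np.linspace(0, geom.cell_radius, n_radial_bins + 1)
        self.xedges = np.linspace(-geom.cell_radius, geom.cell_radius, 2 * n_radial_bins + 1)
        self.times, self.popt, self.part = [], [], []
        self.npool, self.mpool, self.rhist, self.xhist, self.audit = [], [], [], [], []

    def snapshot(self, t: float) -> None:
        sim = self.sim
        M = sim.network.n_species
        self.times.append(t)
        self.popt.append(sim.pop.total_counts())
        live = np.flatnonzero(sim.par.alive)
        ptot = np.zeros(M, dtype=np.int64)
        rh = np.zeros((len(self.redges) - 1, M))
        xh = np.zeros((len(self.xedges) - 1, M))
        if len(live):
            np.add.at(ptot, sim.par.species[live], 1)
            r = np.linalg.norm(sim.par.pos[live] - np.asarray(sim.lattice.geom.center), axis=1)
            for i in range(M):
                seli = sim.par.species[live] == i
                rh[:, i] += np.histogram(r[seli], bins=self.redges)[0]
                xh[:, i] += np.histogram(sim.par.pos[live][seli, 0], bins=self.xedges)[0]
        # population contribution at volume centers
        centers = sim.lattice.centers
        rc = np.linalg.norm(centers - np.asarray(sim.lattice.geom.center), axis=1)
        for i in range(M):
            rh[:, i] += np.histogram(rc, bins=self.redges, weights=sim.pop.counts[:, i])[0]
            xh[:, i] += np.histogram(centers[:, 0], bins=self.xedges,
                                     weights=sim.pop.counts[:, i])[0]
        self.part.append(ptot)
        self.npool.append(sim.par.pools[0].copy())
        self.mpool.append(sim.par.pools[1].copy())
        self.rhist.append(rh)
        self.xhist.append(xh)
        if self.snapshot_dir is not None:
            from . import io as _io
            import os
            os.makedirs(self.snapshot_dir, exist_ok=True)
            _io.write_particle_snapshot(
                sim.par, os.path.join(self.snapshot_dir,
                                      f"particles_{self._snap_index:04d}.csv"), t)
            self._snap_index += 1
        counters = dict(sim.bridge.audit)
        counters.update(sim.audit_particle_events)
        fo, jump, r2, rs = (int(x) for x in sim.pop.event_counters)
        counters.update({"pop_first_order": fo, "pop_jumps": jump,
                         "pop_bimolecular": r2, "pop_surface": rs})
        self.audit.append(counters)

    def finish(self, config) -> TrajectoryRecord:
        return TrajectoryRecord(
            species=[s.name for s in self.sim.network.species],
            times=np.array(self.times),
            population_totals=np.array(self.popt),
            particle_totals=np.array(self.part),
            nucleus_pool=np.array(self.npool),
            membrane_pool=np.array(self.mpool),
            radial_edges=self.redges,
            radial_hist=np.array(self.rhist),
            x_edges=self.xedges,
            x_hist=np.array(self.xhist),
            audit=self.audit,
            config=config,
        )


def build_mode_map(lattice, network, spec) -> ModeMap:
    if isinstance(spec, ModeMap):
        return spec
    if spec == "population":
        return ModeMap.all_population(lattice, network)
    if spec == "particle":
        return ModeMap.all_particle(lattice, network)
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        kind, names = spec
        if kind == "species":
            return ModeMap.per_species(lattice, network, names)
        if kind == "surfaces":
            return ModeMap.particle_near_surfaces(lattice, network, names)
    raise ValueError(f"unknown mode map spec {spec!r}")


def run_simulation(network: ReactionNetwork, config: SimulationConfig) -> TrajectoryRecord:
    """Build lattice, mode map and engines from a config and run it."""
    geom = CellGeometry(config.cell_diameter, config.nucleus_diameter)
    lattice = discretize_cell(geom, config.grid_l, obstacles=config.obstacles)
    mode = build_mode_map(lattice, network, config.mode)
    sim = HybridSimulation(network, lattice, mode, config.dt, config.seed)
    for species, n, where in config.init:
        sim.place(species, n, where)
    return sim.run(
        config.t_end, config.record_interval,
        controller_threshold=config.controller_threshold,
        controller_interval=config.controller_interval,
        convert_every=config.convert_every,
        compact_every=config.compact_every,
        n_radial_bins=config.n_radial_bins,
        snapshot_dir=config.snapshot_dir,
        config=config,
    )
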