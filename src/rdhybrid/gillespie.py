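"""Event-driven population-level engine (spatial next-reaction method).

Each subvolume stores ``2M + R2 + Rs`` absolute next-event times: one
aggregated first-order time per species, one diffusion-jump time per
species, one time per bimolecular channel and one per surface-transfer
channel.  An indexed min-heap over per-volume minima yields the global next
event.  After any state change the affected jump/reaction times are
stretched in proportion to the propensity change instead of being redrawn,
and the aggregated first-order times follow carry/min rules, so waiting-time
statistics survive diffusion jumps and particle/population conversions
without re-randomisation.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .model import ReactionNetwork

INF = math.inf


def draw_waiting_time(a: float, rng) -> float:
    """Exponential waiting time tau = (1/a) ln(1/xi); infinite for a <= 0."""
    if a <= 0.0:
        return INF
    return math.log(1.0 / rng.random()) / a


def rescale_after_change(t_change: float, t_old: float, a_old: float, a_new: float,
                         rng=None) -> float:
    """Stretch the residual waiting time after a propensity change.

    ``t_new = t_change + (a_old / a_new) (t_old - t_change)``.  A channel
    switched off (``a_new = 0``) goes to infinity; a channel switched on from
    zero propensity needs a fresh draw, for which ``rng`` must be given.
    """
    if t_old < t_change:
        raise RuntimeError("stored event time lies in the past: schedule corrupted")
    if a_old <= 0.0 or t_old == INF:
        if a_new <= 0.0:
            return INF
        if rng is None:
            raise ValueError("fresh draw required: pass an rng")
        return t_change + draw_waiting_time(a_new, rng)
    if a_new <= 0.0:
        return INF
    return t_change + (a_old / a_new) * (t_old - t_change)


class BridgeEvent:
    """A pending population-level event that needs particle-level handling."""

    __slots__ = ("code", "volume", "slot", "aux", "time")

    def __init__(self, code, volume, slot, aux, time):
        self.code = code
        self.volume = volume
        self.slot = slot
        self.aux = aux
        self.time = time


class GillespieEngine:
    """Population-level dynamics of a reaction network on a lattice.

    ``mode[v, i]`` is True where species ``i`` is population-tracked in
    subvolume ``v``; molecules in particle-mode slots are owned by the
    particle engine and the population count there is zero.  Events whose
    outcome lands in a particle-mode slot are returned to the caller as
    :class:`BridgeEvent` instead of being executed.
    """

    def __init__(self, network: ReactionNetwork, lattice, mode=None):
        self.network = network
        self.lattice = lattice
        M = network.n_species
        U = lattice.n_volumes
        self.M = M
        self.R2 = network.n_bimolecular
        self.Rs = network.n_surface
        self.n_slots = 2 * M + self.R2 + self.Rs

        self.counts = np.zeros((U, M), dtype=np.int64)
        self.times = np.full((U, self.n_slots), INF)
        self.prop = np.zeros((U, self.n_slots))
        self.vmin_t = np.full(U, INF)
        self.vmin_s = np.full(U, -1, dtype=np.int64)
        self.heap = np.arange(U, dtype=np.int64)
        self.hpos = np.arange(U, dtype=np.int64)
        self.mode = np.ones((U, M), dtype=np.uint8) if mode is None else \
            np.asarray(mode, dtype=np.uint8).reshape(U, M).copy()

        gfac = lattice.jump_factors()
        self.cumg = np.cumsum(gfac, axis=1)
        self.vfree = lattice.free_volume
        self.k1 = network.k1_aggregate
        self.dvec = network.diffusion
        # per-molecule volumetric surface-transfer rates, s^-1
        self.rs_rate = np.zeros((U, self.Rs))
        self.rs_surface = np.zeros(self.Rs, dtype=np.int64)
        self.rs_prod = np.zeros(self.Rs, dtype=np.int64)
        for q, r in enumerate(network.surface_transfers):
            area = lattice.snuc if r.surface == "nucleus" else lattice.smem
            with np.errstate(divide="ignore", invalid="ignore"):
                self.rs_rate[:, q] = np.where(lattice.V > 0, r.rate_constant * area / lattice.V, 0.0)
            self.rs_surface[q] = 0 if r.surface == "nucleus" else 1
            prods = [p for p in r.products]
            self.rs_prod[q] = network.index[prods[0]] if prods else network.index[r.reactants[0]]
        #: absorbed molecule pools: row 0 nucleus, row 1 membrane
        self.pools = np.zeros((2, M), dtype=np.int64)
        self.event_counters = np.zeros(4, dtype=np.int64)
        self.time = 0.0

    # -- propensities -------------------------------------------------------

    def slot_propensity(self, v: int, slot: int) -> float:
        M, R2 = self.M, self.R2
        if slot < M:
            return float(self.counts[v, slot] * self.k1[slot])
        if slot < 2 * M:
            i = slot - M
            return float(self.counts[v, i] * self.dvec[i] * self.cumg[v, 5])
        if slot < 2 * M + R2:
            r = slot - 2 * M
            if self.vfree[v] <= 0:
                return 0.0
            a, b = self.network.r2_a[r], self.network.r2_b[r]
            if a == b:
                n = self.counts[v, a]
                pairs = 0.5 * n * (n - 1)
            else:
                pairs = self.counts[v, a] * self.counts[v, b]
            return float(self.network.r2_kvol[r] * pairs / self.vfree[v])
        q = slot - 2 * M - R2
        return float(self.counts[v, self.network.rs_species[q]] * self.rs_rate[v, q])

    # -- setup --------------------------------------------------------------

    def seed(self, seed: int) -> None:
        """Seed the engine's compiled RNG stream."""
        _kernels.seed_numba(int(seed) & 0x7FFFFFFF)

    def add_molecules(self, species, vol_ids) -> None:
        """Deposit molecules before :meth:`initialize` (no time bookkeeping)."""
        i = species if isinstance(species, (int, np.integer)) \
            else self.network.index[species]
        vol_ids = np.atleast_1d(np.asarray(vol_ids, dtype=np.int64))
        if (vol_ids < 0).any():
            raise ValueError("molecule placed outside the active lattice")
        np.add.at(self.counts[:, i], vol_ids, 1)

    def initialize(self, t0: float = 0.0) -> None:
        """Draw all stored times fresh from the current propensities."""
        self.time = t0
        U = self.lattice.n_volumes
        for v in range(U):
            for s in range(self.n_slots):
                a = self.slot_propensity(v, s)
                self.prop[v, s] = a
                self.times[v, s] = t0 + _kernels.exp_draw(a) if a > 0 else INF
        self._rebuild_schedule()

    def _rebuild_schedule(self) -> None:
        mins = np.min(self.times, axis=1) if self.n_slots else np.full(len(self.times), INF)
        self.vmin_t[:] = np.where(np.isfinite(mins), mins, INF)
        self.vmin_s[:] = np.argmin(self.times, axis=1) if self.n_slots else -1
        self.vmin_s[~np.isfinite(mins)] = -1
        self.vmin_t[self.vmin_s < 0] = INF
        _kernels.heap_build(self.heap, self.hpos, self.vmin_t)

    # -- state maintenance helpers (used by the hybrid bridge) --------------

    def refresh_volume(self, v: int, t: float, fired_slot: int = -1) -> None:
        """Recompute/stretch jump+reaction slots of ``v`` and reorder."""
        _kernels.rescale_volume(
            self.counts, self.times, self.prop, v, t, fired_slot,
            self.k1, self.dvec, self.cumg[:, 5], self.vfree,
            self.network.r2_a, self.network.r2_b, self.network.r2_kvol,
            self.network.rs_species, self.rs_rate,
        )
        _kernels.update_volume_min(self.times, self.vmin_t, self.vmin_s,
                                   self.heap, self.hpos, v)

    def reorder_volume(self, v: int) -> None:
        _kernels.update_volume_min(self.times, self.vmin_t, self.vmin_s,
                                   self.heap, self.hpos, v)

    def remove_one(self, v: int, i: int, t: float) -> float:
        """Remove one random molecule of species i from v (first-order carry).

        Returns the removed molecule's own pending first-order time (the
        stored minimum with probability 1/N, else minimum + Exp(k1)); the
        count is decremented here and :meth:`refresh_volume` applied.
        """
        departing = _kernels.fo_remove_one(self.counts, self.times, v, i, t, self.k1)
        self.counts[v, i] -= 1
        self.refresh_volume(v, t)
        return departing

    def insert_one(self, v: int, i: int, t: float, t_next: float = None) -> None:
        """Insert one molecule of species i into v.

        With ``t_next`` given (a particle entering a population volume, with
        its own pending first-order time, possibly infinite) the stored
        species time min-merges it; without, the molecule is newly created
        and gets a fresh single-molecule draw anchored at ``t``.
        """
        self.counts[v, i] += 1
        if self.k1[i] > 0:
            if t_next is not None:
                if t_next < self.times[v, i]:
                    self.times[v, i] = t_next
            else:
                _kernels.fo_add_one(self.times, v, i, t, self.k1)
        self.refresh_volume(v, t)

    # -- main loop ----------------------------------------------------------

    def advance_until(self, t_horizon: float, bridge_handler=None,
                      max_events: int = 2**62) -> int:
        """Execute pending events up to ``t_horizon``.

        Events that need particle-level handling are passed to
        ``bridge_handler(event)``; the handler is responsible for executing
        them (via the engine helpers) before the loop resumes.  Returns the
        number of executed population events (bridge events excluded).
        """
        before = int(self.event_counters.sum())
        while True:
            code, v, slot, aux = _kernels.gillespie_advance(
                t_horizon, max_events,
                self.counts, self.times, self.prop, self.vmin_t, self.vmin_s,
                self.heap, self.hpos,
                self.lattice.neighbor, self.cumg, self.vfree, self.mode,
                self.k1, self.dvec,
                self.network.fo_offsets, self.network.fo_rate, self.network.fo_delta,
                self.network.r2_a, self.network.r2_b, self.network.r2_kvol,
                self.network.r2_delta,
                self.network.rs_species, self.rs_prod, self.rs_surface,
                self.rs_rate, self.pools, self.event_counters,
            )
            if code == _kernels.ADV_HORIZON:
                break
            if code == _kernels.ADV_MAX_EVENTS:
                raise RuntimeError("population event budget exhausted")
            event = BridgeEvent(code, int(v), int(slot), int(aux), float(self.vmin_t[v]))
            if bridge_handler is None:
                raise RuntimeError(
                    "population event targets a particle-mode slot but no "
                    "bridge handler was provided"
                )
            bridge_handler(event)
        self.time = t_horizon
        return int(self.event_counters.sum()) - before

    # -- views ---------------------------------------------------------------

    def total_counts(self) -> np.ndarray:
        """Per-species population totals over the lattice (pools excluded)."""
        return self.counts.sum(axis=0)

    def subvolume_times(self, v: int) -> np.ndarray:
        return self.times[v].copy()
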