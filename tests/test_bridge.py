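"""Level conversions, time transfer across jumps, cross-level reactions."""

import math

import numpy as np
import pytest
from scipy import stats

from rdhybrid import _kernels
from rdhybrid.bridge import HybridBridge, ModeMap
from rdhybrid.geometry import box_lattice
from rdhybrid.model import ReactionNetwork, ReactionSpec, SpeciesSpec
from rdhybrid.simulate import HybridSimulation, SimulationConfig, run_simulation

INF = math.inf


def make_sim(net, shape=(2, 1, 1), l=1.0, dt=1e-3, seed=1, population=True):
    lat = box_lattice(shape, l, periodic=False)
    mode = ModeMap.all_population(lat, net) if population else \
        ModeMap.all_particle(lat, net)
    sim = HybridSimulation(net, lat, mode, dt=dt, seed=seed)
    sim.initialize()
    return sim


class TestConvertToPopulation:
    def test_empty_volume(self, decay_network):
        sim = make_sim(decay_network, population=False)
        sim.bridge.convert_to_population(0, ["A"], 0.0)
        assert sim.pop.counts[0, 0] == 0
        assert sim.pop.times[0, 0] == INF

    def test_species_time_is_min_of_particle_times(self, decay_network):
        sim = make_sim(decay_network, population=False)
        pos = np.array([[0.5, 0.5, 0.5]] * 3)
        sim.par.add_particles(0, pos, t_next=np.array([5.0, 2.0, 7.0]))
        sim.bridge.convert_to_population(0, ["A"], 0.0)
        assert sim.pop.counts[0, 0] == 3
        assert sim.pop.times[0, 0] == 2.0
        assert sim.par.n_alive == 0


class TestConvertToParticles:
    def test_zero_count_clears_slot(self, decay_network):
        sim = make_sim(decay_network)
        sim.bridge.convert_to_particles(0, ["A"], 0.0)
        assert sim.par.n_alive == 0
        assert sim.pop.times[0, 0] == INF

    def test_single_molecule_preserves_exact_time(self, decay_network):
        sim = make_sim(decay_network)
        sim.pop.counts[0, 0] = 1
        sim.pop.times[0, 0] = 3.75
        sim.bridge.convert_to_particles(0, ["A"], 0.0)
        assert sim.par.n_alive == 1
        assert float(sim.par.t_next[sim.par.alive][0]) == 3.75

    def test_other_particles_anchored_beyond_minimum(self, decay_network):
        """The first particle inherits the stored time; all others must lie
        beyond it, with Exp(k1) residuals (order statistics given the min)."""
        residuals = []
        for seed in range(300):
            sim = make_sim(decay_network, seed=seed)
            sim.pop.counts[0, 0] = 4
            m = 1.25
            sim.pop.times[0, 0] = m
            sim.bridge.convert_to_particles(0, ["A"], 0.0)
            ts = np.sort(sim.par.t_next[sim.par.alive])
            assert ts[0] == m
            residuals.extend(ts[1:] - m)
        assert stats.kstest(residuals, "expon", args=(0, 1.0)).pvalue > 0.01

    def test_round_trip_preserves_min(self, decay_network):
        sim = make_sim(decay_network)
        sim.pop.counts[0, 0] = 6
        sim.pop.times[0, 0] = 0.8
        sim.bridge.convert_to_particles(0, ["A"], 0.0)
        sim.bridge.convert_to_population(0, ["A"], 0.0)
        assert sim.pop.counts[0, 0] == 6
        assert sim.pop.times[0, 0] == 0.8


class TestJumpTimeTransfer:
    def test_carrier_frequency_is_one_over_n(self, decay_network):
        """fo_remove_one returns the stored minimum with probability 1/N."""
        _kernels.seed_numba(2024)
        n, trials, carried = 4, 100000, 0
        counts = np.zeros((1, 1), dtype=np.int64)
        k1 = np.array([1.0])
        for _ in range(trials):
            counts[0, 0] = n
            times = np.array([[0.5]])
            if _kernels.fo_remove_one(counts, times, 0, 0, 0.0, k1) == 0.5:
                carried += 1
        p = carried / trials
        se = math.sqrt(0.25 * 0.75 / trials)
        assert abs(p - 0.25) < 3 * se

    def test_single_molecule_always_carries(self, decay_network):
        _kernels.seed_numba(7)
        counts = np.array([[1]], dtype=np.int64)
        times = np.array([[0.9]])
        out = _kernels.fo_remove_one(counts, times, 0, 0, 0.0, np.array([2.0]))
        assert out == 0.9
        assert times[0, 0] == INF  # no molecules left to redraw from

    def test_noncarrier_time_lies_beyond_minimum(self):
        _kernels.seed_numba(99)
        k1 = np.array([1.0])
        for _ in range(200):
            counts = np.array([[5]], dtype=np.int64)
            times = np.array([[2.0]])
            out = _kernels.fo_remove_one(counts, times, 0, 0, 0.0, k1)
            assert out >= 2.0  # memoryless residual anchored at the stored min

    def test_decay_rate_invariant_under_jumps(self, decay_network):
        """Two-volume decay+diffusion still follows exp(-kt)."""
        lat = box_lattice((2, 1, 1), 1.0, periodic=False)
        total = survivors = 0
        from rdhybrid.gillespie import GillespieEngine
        for seed in range(6):
            eng = GillespieEngine(decay_network, lat)
            eng.seed(500 + seed)
            eng.counts[:, 0] = 1500
            total += eng.counts.sum()
            eng.initialize()
            eng.advance_until(1.0)
            survivors += eng.counts.sum()
        p = survivors / total
        se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / total)
        assert abs(p - math.exp(-1)) < 3 * se


class TestParticlePopulationCrossings:
    def test_particle_entering_population_volume_min_merges(self, decay_network):
        sim = make_sim(decay_network)
        sim.pop.counts[0, 0] = 3
        sim.pop.times[0, 0] = 2.0
        idx = sim.par.add_particles(0, np.array([[0.5, 0.5, 0.5]]),
                                    t_next=np.array([1.0]))[0]
        sim.bridge.particle_handover(idx, 0, 0.0)
        assert sim.pop.counts[0, 0] == 4
        assert sim.pop.times[0, 0] == 1.0

    def test_particle_with_infinite_time_leaves_slot(self, decay_network):
        sim = make_sim(decay_network)
        sim.pop.counts[0, 0] = 3
        sim.pop.times[0, 0] = 2.0
        idx = sim.par.add_particles(0, np.array([[0.5, 0.5, 0.5]]),
                                    t_next=np.array([INF]))[0]
        sim.bridge.particle_handover(idx, 0, 0.0)
        assert sim.pop.times[0, 0] == 2.0

    def test_jump_into_particle_volume_single_molecule_carries(self, decay_network):
        lat = box_lattice((2, 1, 1), 1.0, periodic=False)
        mode = ModeMap(lat, decay_network)
        mode.population[1, 0] = 0  # volume 1 particle-mode
        sim = HybridSimulation(decay_network, lat, mode, dt=1e-3, seed=3)
        sim.pop.counts[0, 0] = 1
        sim.initialize()
        stored = float(sim.pop.times[0, 0])
        # drive until the single molecule jumps into the particle volume
        t = 0.0
        while sim.par.n_alive == 0 and t < 5.0:
            t += 0.05
            sim.pop.advance_until(min(t, stored - 1e-9),
                                  sim.bridge.handle_population_event)
            if t >= stored:
                break
        if sim.par.n_alive:
            assert float(sim.par.t_next[sim.par.alive][0]) == stored
            assert sim.pop.counts[0, 0] == 0

    def test_round_trip_conserves_molecules(self, decay_network):
        net = ReactionNetwork([SpeciesSpec("A", 10.0, 0.005)], [])
        lat = box_lattice((2, 1, 1), 1.0, periodic=False)
        mode = ModeMap(lat, net)
        mode.population[1, 0] = 0
        sim = HybridSimulation(net, lat, mode, dt=1e-3, seed=5)
        sim.pop.counts[0, 0] = 500
        sim.initialize()
        for s in range(200):
            sim.step(s)
        assert sim.pop.counts.sum() + sim.par.n_alive == 500

    def test_level_exclusivity(self, decay_network):
        """Population counts stay zero wherever the species is particle-mode."""
        net = ReactionNetwork([SpeciesSpec("A", 10.0, 0.005)], [])
        lat = box_lattice((3, 1, 1), 1.0, periodic=False)
        mode = ModeMap(lat, net)
        mode.population[1, 0] = 0
        sim = HybridSimulation(net, lat, mode, dt=1e-3, seed=6)
        sim.pop.counts[0, 0] = 300
        sim.pop.counts[2, 0] = 300
        sim.initialize()
        for s in range(100):
            sim.step(s)
            assert sim.pop.counts[1, 0] == 0
            census = sim.par.census()
            assert census[0, 0] == 0 and census[2, 0] == 0


class TestCrossLevelReaction:
    def test_quasi_first_order_rate_value(self):
        """k_i,nu = k_ij N_j / V: reference arithmetic for N=30, V=0.125."""
        net = ReactionNetwork(
            [SpeciesSpec("A", 10.0, 0.01), SpeciesSpec("B", 10.0, 0.01)],
            [ReactionSpec(("A", "B"), (), 1e7)],
        )
        k_sim = float(net.r2_kvol[0])           # um^3/s per pair
        rate = k_sim * 30 / 0.125               # s^-1
        assert rate == pytest.approx(3.99, abs=0.01)
        p = 1 - math.exp(-rate * 2.6e-5)
        assert p == pytest.approx(1.036e-4, rel=1e-3)

    def test_no_partners_no_reaction(self, ab_network):
        lat = box_lattice((1, 1, 1), 1.0)
        mode = ModeMap.per_species(lat, ab_network, ["A"])
        sim = HybridSimulation(ab_network, lat, mode, dt=1e-4, seed=2)
        sim.par.add_particles(0, np.array([[0.5, 0.5, 0.5]]), t_next=np.array([INF]))
        sim.initialize()
        assert sim.bridge.cross_level_attempts(0.0) == 0


class TestModeController:
    def test_zero_threshold_no_switches(self, decay_network):
        sim = make_sim(decay_network)
        sim.pop.counts[0, 0] = 5
        assert sim.bridge.mode_controller(0.0, 0) == 0

    def test_single_switch_on_decay_through_threshold(self):
        """A population decaying 100 -> 0 with threshold 10 switches each
        volume to particles exactly once (hysteresis prevents flapping)."""
        net = ReactionNetwork([SpeciesSpec("A", 1.0, 0.005)],
                              [ReactionSpec(("A",), (), 1.0)])
        cfg = SimulationConfig(cell_diameter=4.0, nucleus_diameter=0.0, grid_l=1,
                               dt=0.01, t_end=4.0, seed=17, mode="population",
                               init=[("A", 100, "cytoplasm")], record_interval=1.0,
                               controller_threshold=10, controller_interval=10)
        rec = run_simulation(net, cfg)
        assert rec.audit[-1]["conversions_to_particles"] == 1
        assert rec.audit[-1]["conversions_to_population"] == 0
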