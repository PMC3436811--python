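"""Brownian dynamics, boundary handling, collisions and per-particle events."""

import math

import numpy as np
import pytest
from scipy import stats

from rdhybrid import _kernels
from rdhybrid.geometry import CellGeometry, discretize_cell, uniform_in_cytoplasm
from rdhybrid.model import ReactionNetwork, ReactionSpec, SpeciesSpec
from rdhybrid.particles import (ParticleEngine, bimolecular_probability, brownian_step,
                                schedule_first_order, surface_transfer_probability)
from rdhybrid.simulate import HybridSimulation, SimulationConfig, run_simulation
from rdhybrid.bridge import ModeMap


class TestBrownianStep:
    def test_zero_diffusion_is_identity(self, rng):
        x = np.array([[1.0, -2.0, 0.5]])
        assert (brownian_step(x, 0.0, 1e-4, rng) == x).all()

    def test_displacement_variance(self, rng):
        # per-axis variance 2 D dt; D=10, dt=2.6e-5 -> 5.2e-4 um^2
        d, dt, n = 10.0, 2.6e-5, 100000
        disp = brownian_step(np.zeros((n, 3)), d, dt, rng)
        var = disp.var(axis=0)
        se = 5.2e-4 * math.sqrt(2.0 / n)
        assert np.all(np.abs(var - 5.2e-4) < 3 * se)

    def test_msd_linear_in_steps(self, rng):
        d, dt, n, steps = 5.0, 1e-4, 5000, 40
        x = np.zeros((n, 3))
        for _ in range(steps):
            x = brownian_step(x, d, dt, rng)
        sq = (x**2).sum(axis=1)
        expected = 6 * d * dt * steps
        assert abs(sq.mean() - expected) < 3 * sq.std(ddof=1) / math.sqrt(n)


class TestBoundaries:
    @pytest.fixture
    def engine(self, cell_lattice):
        net = ReactionNetwork([SpeciesSpec("A", 10.0, 0.01)], [])
        return ParticleEngine(net, cell_lattice)

    def _step_with_normals(self, engine, normals, uniforms=None):
        n = len(engine.ids)
        mode = np.zeros((engine.lattice.n_volumes, 1), dtype=np.uint8)
        codes = np.zeros(n, dtype=np.int64)
        target = np.zeros(n, dtype=np.int64)
        if uniforms is None:
            uniforms = np.ones(n)
        box = np.array(engine.lattice.vol_id.shape, dtype=float) * engine.lattice.l
        _kernels.step_particles_cell(
            engine.pos, engine.species, engine.alive, normals, uniforms,
            np.array([math.sqrt(2 * 10.0 * 1e-4)]), engine.r_cell_eff, engine.r_nuc,
            np.zeros(1), np.zeros(1), np.ones(1), engine.lattice.x0, engine.lattice.l,
            engine.lattice.vol_id, mode, codes, target, True, False, box)
        return codes

    def test_interior_move_accepted(self, engine, rng):
        engine.add_particles(0, np.array([[3.0, 0.0, 0.0]]), rng=rng)
        old = engine.pos[0].copy()
        self._step_with_normals(engine, np.array([[1.0, 0.0, 0.0]]))
        assert not np.allclose(engine.pos[0], old)

    def test_step_beyond_membrane_rejected(self, engine, rng):
        engine.add_particles(0, np.array([[4.98, 0.0, 0.0]]), rng=rng)
        old = engine.pos[0].copy()
        self._step_with_normals(engine, np.array([[200.0, 0.0, 0.0]]))
        assert np.allclose(engine.pos[0], old)  # stays in place, no reflection

    def test_step_into_nucleus_rejected_without_import(self, engine, rng):
        engine.add_particles(0, np.array([[1.52, 0.0, 0.0]]), rng=rng)
        old = engine.pos[0].copy()
        self._step_with_normals(engine, np.array([[-200.0, 0.0, 0.0]]))
        assert np.allclose(engine.pos[0], old)

    def test_corrupt_state_detected(self, engine, rng):
        engine.add_particles(0, np.array([[0.0, 0.0, 0.0]]), rng=rng)  # inside nucleus
        with pytest.raises(RuntimeError, match="illegal position"):
            engine.step(1e-4, rng)

    def test_equilibrium_density_uniform(self, cell_lattice, rng):
        """Rejection at boundaries must preserve the uniform measure."""
        net = ReactionNetwork([SpeciesSpec("A", 10.0, 0.0)], [])
        eng = ParticleEngine(net, cell_lattice)
        n = 10000
        eng.add_particles(0, uniform_in_cytoplasm(cell_lattice, n, rng), rng=rng)
        for _ in range(300):
            eng.step(1e-3, rng)
        r = np.linalg.norm(eng.pos[eng.alive], axis=1)
        edges = np.linspace(1.5, 5.0, 11)
        observed = np.histogram(r, bins=edges)[0]
        shell = edges**3
        p = np.diff(shell) / (shell[-1] - shell[0])
        assert stats.chisquare(observed, n * p).pvalue > 0.01


class TestSurfaceTransfer:
    def test_zero_permeability_never_transfers(self):
        assert surface_transfer_probability(0.0, 1e-4, 10.0) == 0.0

    def test_probability_linear_in_permeability(self):
        p1 = surface_transfer_probability(1.8, 2.6e-5, 10.0)
        p2 = surface_transfer_probability(3.6, 2.6e-5, 10.0)
        assert p2 == pytest.approx(2 * p1)
        assert p1 == pytest.approx(1.8 * math.sqrt(math.pi * 2.6e-5 / 10.0))

    def test_clipped_at_one(self):
        assert surface_transfer_probability(1e6, 1e-2, 1.0) == 1.0


class TestCollisions:
    @pytest.fixture
    def engine(self, ab_network, cell_lattice):
        return ParticleEngine(ab_network, cell_lattice)

    def test_single_particle_no_pairs(self, engine, rng):
        engine.add_particles(0, np.array([[3.0, 0, 0]]), rng=rng)
        assert len(engine.detect_collisions()) == 0

    def test_distance_strictly_less_than_sigma(self, engine, rng):
        sigma = 0.02
        engine.add_particles(0, np.array([[3.0, 0, 0]]), rng=rng)
        engine.add_particles(1, np.array([[3.0 + sigma, 0, 0]]), rng=rng)   # exactly sigma
        assert len(engine.detect_collisions()) == 0
        engine.add_particles(1, np.array([[3.0 + 0.99 * sigma, 0, 0]]), rng=rng)
        pairs = engine.detect_collisions()
        assert len(pairs) == 1

    def test_same_species_pairs_not_reported(self, engine, rng):
        engine.add_particles(0, np.array([[3.0, 0, 0], [3.001, 0, 0]]), rng=rng)
        assert len(engine.detect_collisions()) == 0  # no A+A channel

    def test_agreement_with_brute_force(self, engine, cell_lattice, rng):
        pos = uniform_in_cytoplasm(cell_lattice, 200, rng)
        # cluster them to force contacts
        pos = 3.0 + 0.05 * (pos - pos.mean(axis=0)) / 5.0
        engine.add_particles(0, pos[:100], rng=rng)
        engine.add_particles(1, pos[100:], rng=rng)
        got = {tuple(sorted(map(int, p))) for p in engine.detect_collisions()}
        sigma = engine.network.sigma
        expect = set()
        for a in range(200):
            for b in range(a + 1, 200):
                s = sigma[engine.species[a], engine.species[b]]
                if s > 0 and np.linalg.norm(engine.pos[a] - engine.pos[b]) < s:
                    expect.add((a, b))
        assert got == expect


class TestBimolecularProbability:
    def test_zero_rate(self):
        assert bimolecular_probability(0.0, 0.01, 1e-4) == 0.0

    def test_reference_value(self):
        # k=1e7 M^-1 s^-1, sigma=0.01 um, dt=2.6e-5 s: pair volume rate over
        # the collision sphere gives P ~ 0.103
        p = bimolecular_probability(1e7, 0.01, 2.6e-5)
        k_sim = 1e7 / (6.02214e23 * 1e-15)
        v_sigma = 4 / 3 * math.pi * 0.01**3
        assert p == pytest.approx(k_sim * 2.6e-5 / v_sigma, rel=1e-12)
        assert p == pytest.approx(0.103, abs=0.001)

    def test_clipped_with_warning(self, caplog):
        assert bimolecular_probability(1e12, 0.005, 1e-3) == 1.0


class TestFirstOrderScheduling:
    def test_no_channel_infinite(self, rng):
        assert schedule_first_order(0.0, 5.0, rng) == math.inf

    def test_mean_waiting_time(self, rng):
        draws = np.array([schedule_first_order(2.0, 0.0, rng) for _ in range(1000)])
        # vectorised draw for the bulk of the sample
        draws = np.concatenate([draws, rng.exponential(0.5, 99000)])
        se = 0.5 / math.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_min_of_population_is_exponential_in_n(self, rng):
        n_mol, k1, reps = 30, 2.0, 3000
        mins = rng.exponential(1 / k1, size=(reps, n_mol)).min(axis=1)
        assert stats.kstest(mins, "expon", args=(0, 1 / (n_mol * k1))).pvalue > 0.01

    def test_pure_decay_survival(self, decay_network):
        cfg = SimulationConfig(cell_diameter=6, nucleus_diameter=0, grid_l=3,
                               dt=2e-3, t_end=1.0, seed=7, mode="particle",
                               init=[("A", 8000, "cytoplasm")], record_interval=0.5)
        rec = run_simulation(decay_network, cfg)
        surv = rec.totals()[-1, 0] / 8000
        se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / 8000)
        assert abs(surv - math.exp(-1)) < 3 * se

    def test_event_order_ascending(self, decay_network, cell_lattice, rng):
        eng = ParticleEngine(decay_network, cell_lattice)
        eng.add_particles(0, uniform_in_cytoplasm(cell_lattice, 50, rng), rng=rng)
        due = eng.first_order_due(math.inf)
        times = eng.t_next[due]
        assert (np.diff(times) >= 0).all()


class TestConservation:
    def test_no_reactions_conserves_particles(self, cell_lattice, rng):
        net = ReactionNetwork([SpeciesSpec("A", 10.0, 0.0)], [])
        mode = ModeMap.all_particle(cell_lattice, net)
        sim = HybridSimulation(net, cell_lattice, mode, dt=1e-3, seed=1)
        sim.place("A", 5000, "cytoplasm")
        rec = sim.run(0.2, record_interval=0.05)
        assert (rec.totals()[:, 0] == 5000).all()

    def test_census_matches_positions(self, cell_lattice, rng):
        net = ReactionNetwork([SpeciesSpec("A", 10.0, 0.0)], [])
        eng = ParticleEngine(net, cell_lattice)
        eng.add_particles(0, uniform_in_cytoplasm(cell_lattice, 1000, rng), rng=rng)
        for _ in range(20):
            eng.step(1e-3, rng)
        census = eng.census()
        assert census.sum() == 1000
        vols = cell_lattice.locate(eng.pos[eng.alive])
        assert (np.bincount(vols, minlength=cell_lattice.n_volumes)
                == census[:, 0]).all()
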