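"""Built-in scenarios, output writers, configuration files and the CLI."""

import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from rdhybrid import io as rio
from rdhybrid.cli import main as cli_main
from rdhybrid.model import ReactionNetwork, ReactionSpec, SpeciesSpec
from rdhybrid.scenarios import (mapk_network, scenario_ab_annihilation,
                                scenario_crowding, scenario_mapk)
from rdhybrid.simulate import SimulationConfig, run_simulation


class TestRunSimulation:
    def test_zero_time_echoes_initial_state(self, decay_network):
        cfg = SimulationConfig(cell_diameter=6, nucleus_diameter=0, grid_l=2,
                               dt=1e-3, t_end=0.0, seed=1, mode="population",
                               init=[("A", 100, "cytoplasm")])
        rec = run_simulation(decay_network, cfg)
        assert rec.times.tolist() == [0.0]
        assert rec.totals()[0, 0] == 100

    def test_same_seed_bit_identical(self, ab_network):
        cfg = dict(cell_diameter=6, nucleus_diameter=0, grid_l=3, dt=5e-4,
                   t_end=0.05, seed=42, mode=("species", ["A"]),
                   init=[("A", 300, "cytoplasm"), ("B", 300, "cytoplasm")],
                   record_interval=0.01)
        r1 = run_simulation(ab_network, SimulationConfig(**cfg))
        r2 = run_simulation(ab_network, SimulationConfig(**cfg))
        assert (r1.totals() == r2.totals()).all()
        assert (r1.radial_hist == r2.radial_hist).all()
        r3 = run_simulation(ab_network, SimulationConfig(**{**cfg, "seed": 43}))
        assert not (r1.totals() == r3.totals()).all()

    def test_decay_any_mode_map(self, decay_network):
        for mode in ("population", "particle"):
            cfg = SimulationConfig(cell_diameter=6, nucleus_diameter=0, grid_l=2,
                                   dt=2e-3, t_end=1.0, seed=9, mode=mode,
                                   init=[("A", 4000, "cytoplasm")], record_interval=0.5)
            rec = run_simulation(decay_network, cfg)
            surv = rec.totals()[-1, 0] / 4000
            se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / 4000)
            assert abs(surv - math.exp(-1)) < 3 * se


class TestAnnihilationScenario:
    def test_zero_rate_counts_constant(self):
        recs = scenario_ab_annihilation(n_per_species=200, L=4, modes=("hybrid",),
                                        k_on=0.0, dt=1e-3, t_end=0.05, seed=3)
        rec = recs["hybrid"]
        assert (rec.totals() == 200).all()

    def test_minimum_molecules(self):
        with pytest.raises(ValueError):
            scenario_ab_annihilation(n_per_species=1)

    def test_shell_initial_conditions(self):
        recs = scenario_ab_annihilation(n_per_species=300, L=10, modes=("particle",),
                                        k_on=0.0, dt=1e-4, t_end=1e-4, seed=8)
        rec = recs["particle"]
        redges = rec.radial_edges
        a_hist = rec.radial_hist[0, :, 0]
        b_hist = rec.radial_hist[0, :, 1]
        # A on the membrane shell (outermost bins), B at the nuclear surface
        assert a_hist[redges[1:] > 4.5].sum() == 300
        assert b_hist[(redges[:-1] >= 1.4) & (redges[1:] < 2.1)].sum() == 300


class TestMapkScenario:
    def test_zero_import_rate_keeps_nucleus_empty(self):
        net = mapk_network(use_effective_first_order=True, k_import=0.0)
        from rdhybrid.simulate import run_simulation as rs
        cfg = SimulationConfig(cell_diameter=10, nucleus_diameter=3, grid_l=4,
                               dt=1e-3, t_end=0.2, seed=4, mode="population",
                               init=[("MAPKpp", 500, "membrane")], record_interval=0.1)
        rec = rs(net, cfg)
        assert rec.nucleus_pool.sum() == 0

    def test_wellmixed_two_state_plateau(self):
        """L=1 population with effective rates (0.1, 1.0): the nuclear
        fraction approaches k_in/(k_in + k_p') = 1/11."""
        rec = scenario_mapk(n_mapk=10000, L=1, mode="population",
                            use_effective_first_order=True, dt=1e-3, t_end=10.0,
                            record_interval=2.0, seed=5)
        i = rec.species_index("MAPKpp")
        frac = rec.nucleus_pool[-1, i] / 10000
        p = 1 / 11
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 10000)

    def test_counts_conserved_across_pools(self):
        rec = scenario_mapk(n_mapk=500, L=6, mode="surfaces",
                            use_effective_first_order=True, dt=1e-3, t_end=0.2,
                            record_interval=0.1, seed=6)
        assert (rec.totals().sum(axis=1) == 500).all()


class TestCrowdingScenario:
    def test_phi_one_ratio_unity(self):
        r = scenario_crowding(1.0, "population", n_walkers=1500, seed=2)
        assert r == pytest.approx(1.0, abs=0.05)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            scenario_crowding(0.9, "quantum")


@pytest.fixture
def small_record(decay_network):
    cfg = SimulationConfig(cell_diameter=6, nucleus_diameter=0, grid_l=2,
                           dt=1e-3, t_end=0.02, seed=1, mode="population",
                           init=[("A", 50, "cytoplasm")], record_interval=0.01)
    return run_simulation(decay_network, cfg)


class TestOutputs:
    def test_totals_are_row_sums_of_regions(self, small_record, tmp_path):
        df = rio.timeseries_frame(small_record)
        total = df["A_total"]
        parts = df[["A_population", "A_particles", "A_nucleus", "A_membrane"]].sum(axis=1)
        assert (total == parts).all()

    def test_round_trip(self, small_record, tmp_path):
        paths = rio.write_outputs(small_record, str(tmp_path / "out"))
        df = rio.read_timeseries(paths["timeseries"])
        assert np.allclose(df["A_total"].to_numpy(), small_record.totals()[:, 0])
        meta = json.loads(open(paths["metadata"]).read())
        assert meta["species"] == ["A"]
        assert meta["config"]["seed"] == 1

    def test_unwritable_path_rejected_before_compute(self, small_record):
        with pytest.raises(FileNotFoundError):
            rio._check_writable("/nonexistent-dir-xyz/file.tsv")

    def test_particle_snapshot(self, cell_lattice, rng, tmp_path):
        net = ReactionNetwork([SpeciesSpec("A", 1.0)], [])
        from rdhybrid.particles import ParticleEngine
        from rdhybrid.geometry import uniform_in_cytoplasm
        eng = ParticleEngine(net, cell_lattice)
        eng.add_particles(0, uniform_in_cytoplasm(cell_lattice, 10, rng), rng=rng)
        path = tmp_path / "snap.csv"
        rio.write_particle_snapshot(eng, str(path), 0.5)
        import pandas as pd
        df = pd.read_csv(path)
        assert len(df) == 10
        assert set(df.columns) == {"id", "species", "x", "y", "z", "t"}


CONFIG_YAML = """
species:
  - {name: A, D: 10.0, radius: 0.005}
reactions:
  - {reactants: [A], products: [], rate: 1.0}
geometry: {cell_diameter: 6.0, nucleus_diameter: 0.0, L: 2}
run: {dt: 1.0e-3, t_end: 0.02, seed: 7, record_interval: 0.01}
modes: population
init:
  - {species: A, count: 40, where: cytoplasm}
"""


class TestConfigAndCli:
    def test_load_config(self, tmp_path):
        p = tmp_path / "model.yaml"
        p.write_text(CONFIG_YAML)
        net, cfg = rio.load_config(p)
        assert net.n_species == 1
        assert cfg.seed == 7
        rec = run_simulation(net, cfg)
        assert rec.totals()[0, 0] == 40

    def test_config_requires_seed(self, tmp_path):
        p = tmp_path / "model.yaml"
        p.write_text(CONFIG_YAML.replace("seed: 7, ", ""))
        with pytest.raises(ValueError, match="seed"):
            rio.load_config(p)

    def test_cli_simulate(self, tmp_path):
        p = tmp_path / "model.yaml"
        p.write_text(CONFIG_YAML)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["simulate", str(p), "--seed", "11",
                                          "--out-dir", str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        out = json.loads(result.output)
        assert "timeseries" in out["outputs"]

    def test_cli_crowding_scenario(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["scenario", "crowding", "--phi", "1.0",
                                          "--seed", "3"])
        assert result.exit_code == 0, result.output
        out = json.loads(result.output)
        assert out["D_eff_over_D0"] == pytest.approx(1.0, abs=0.05)


class TestMembraneAdsorption:
    def test_particles_bind_to_membrane_pool(self, cell_lattice, rng):
        from rdhybrid.geometry import uniform_on_sphere
        from rdhybrid.bridge import ModeMap
        from rdhybrid.simulate import HybridSimulation
        net = ReactionNetwork(
            [SpeciesSpec("R", 10.0, 0.005), SpeciesSpec("Rb", 0.0, 0.005,
                                                        membrane_bound=True)],
            [ReactionSpec(("R",), ("Rb",), 1.0, kind="surface_transfer",
                          surface="membrane")],
        )
        mode = ModeMap.all_particle(cell_lattice, net)
        sim = HybridSimulation(net, cell_lattice, mode, dt=1e-3, seed=9)
        n = 2000
        sim.par.add_particles(0, uniform_on_sphere(n, 4.9, np.random.default_rng(1)),
                              t_next=np.full(n, np.inf))
        sim.initialize()
        for s in range(200):
            sim.step(s)
        bound = sim.par.pools[1, net.index["Rb"]]
        assert bound > 0
        assert sim.par.n_alive + bound == n


class TestMapkHybridAgreement:
    def test_hybrid_uptake_matches_all_particle(self):
        """Scaled-down nuclear-import scenario: particle tracking near the
        membrane and nucleus with a population interior gives the same mean
        uptake as tracking every molecule, within 3 pooled SE."""
        import math
        reps, n, T = 6, 1000, 10
        curves = {}
        for mode in ("particle", "surfaces"):
            runs = []
            for rep in range(reps):
                rec = scenario_mapk(n_mapk=n, L=20, mode=mode,
                                    use_effective_first_order=True,
                                    dt=1e-4, t_end=2.5, record_interval=0.25,
                                    seed=3000 + rep)
                i = rec.species_index("MAPKpp")
                runs.append(rec.nucleus_pool[:, i].astype(float))
            curves[mode] = np.array(runs)
        a, b = curves["particle"], curves["surfaces"]
        se = np.sqrt(a.var(0, ddof=1) / reps + b.var(0, ddof=1) / reps)
        z = np.abs(a.mean(0) - b.mean(0))[1:] / np.where(se[1:] > 0, se[1:], np.inf)
        assert z.max() <= 3.0, (a.mean(0), b.mean(0), z)
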