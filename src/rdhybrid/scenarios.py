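"""Built-in study scenarios.

- ``scenario_ab_annihilation``: two species released from opposite surfaces
  (A from the plasma membrane, B from the nuclear surface) annihilate on
  contact; runnable with both species as particles, both as populations, or
  A as particles against a population-level B.  The mean trajectories of
  the three variants agree, which is the central validation of the hybrid
  coupling.
- ``scenario_mapk``: nuclear import of active MAPK released at the plasma
  membrane while a cytoplasmic phosphatase deactivates it; the fraction of
  molecules reaching the nucleus probes transport against deactivation.
- ``scenario_crowding``: pure diffusion through a crowded volume, returning
  the effective long-range diffusion ratio D_eff / D_0.
"""

from __future__ import annotations

import numpy as np

from .geometry import (CellGeometry, ObstacleMap, box_lattice, estimate_effective_diffusion,
                       generate_obstacle_map, run_box_walkers, run_lattice_tracers)
from .model import ReactionSpec, ReactionNetwork, SpeciesSpec, concentration_to_count
from .simulate import SimulationConfig, run_simulation

AB_MODES = ("particle", "population", "hybrid")


def ab_network(k_on: float = 1e8, diffusion: float = 10.0, radius: float = 0.01) -> ReactionNetwork:
    """A + B -> 0 with equal diffusion and radii; rate in M^-1 s^-1."""
    return ReactionNetwork(
        [SpeciesSpec("A", diffusion, radius), SpeciesSpec("B", diffusion, radius)],
        [ReactionSpec(("A", "B"), (), k_on)],
    )


def scenario_ab_annihilation(n_per_species: int = 2000, L: int = 10,
                             modes=AB_MODES, *, k_on: float = 1e8,
                             diffusion: float = 10.0, radius: float = 0.01,
                             dt: float = 1e-4, t_end: float = 1.5,
                             record_interval: float = 0.15, seed: int = 0,
                             cell_diameter: float = 10.0, nucleus_diameter: float = 3.0):
    """Annihilation test case: A starts on the plasma membrane, B on the
    nuclear surface.  Returns ``{mode: TrajectoryRecord}`` for the requested
    mode combinations (``hybrid`` = A particle-tracked, B population)."""
    if n_per_species < 2:
        raise ValueError("need at least 2 molecules per species")
    net = ab_network(k_on, diffusion, radius)
    out = {}
    for mode in modes:
        mode_spec = {"particle": "particle", "population": "population",
                     "hybrid": ("species", ["A"])}[mode]
        cfg = SimulationConfig(
            cell_diameter=cell_diameter, nucleus_diameter=nucleus_diameter,
            grid_l=L, dt=dt, t_end=t_end, seed=seed, mode=mode_spec,
            init=[("A", n_per_species, "membrane"), ("B", n_per_species, "nucleus_surface")],
            record_interval=record_interval,
        )
        out[mode] = run_simulation(net, cfg)
    return out


def mapk_network(*, use_effective_first_order: bool = False,
                 k_p: float = 1e7, k_p_eff: float = 1.0,
                 k_import: float = 1.8, d_mapk: float = 10.0,
                 d_phos: float = 10.0, radius: float = 0.005) -> ReactionNetwork:
    """Active-MAPK nuclear import with cytoplasmic deactivation.

    Dephosphorylation is either the explicit bimolecular channel
    MAPKpp + P -> MAPK + P (``k_p`` in M^-1 s^-1) or the collapsed
    pseudo-first-order channel MAPKpp -> MAPK with ``k_p_eff = k_p [P]``.
    Nuclear import is a surface transfer with permeability ``k_import``.
    """
    species = [
        SpeciesSpec("MAPKpp", d_mapk, radius, nuclear_capable=True),
        SpeciesSpec("MAPK", d_mapk, radius),
    ]
    reactions = [
        ReactionSpec(("MAPKpp",), ("MAPKpp",), k_import,
                     kind="surface_transfer", surface="nucleus"),
    ]
    if use_effective_first_order:
        reactions.append(ReactionSpec(("MAPKpp",), ("MAPK",), k_p_eff))
    else:
        species.append(SpeciesSpec("P", d_phos, radius))
        reactions.append(ReactionSpec(("MAPKpp", "P"), ("MAPK", "P"), k_p, catalytic=True))
    return ReactionNetwork(species, reactions)


def scenario_mapk(n_mapk: int = 10000, n_phos: int | None = None, L: int = 10,
                  mode="surfaces", *, use_effective_first_order: bool = False,
                  dt: float = 2.6e-5, t_end: float = 10.0,
                  record_interval: float = 0.25, seed: int = 0,
                  cell_diameter: float = 10.0, nucleus_diameter: float = 3.0,
                  phos_concentration: float = 1e-7):
    """Nuclear-import scenario; returns a TrajectoryRecord whose
    ``nucleus_pool`` column for MAPKpp counts arrivals in the nucleus.

    ``mode``: "surfaces" (particle near membrane+nucleus, population
    elsewhere), "particle", or "population"; the phosphatase, when explicit,
    is always population-mode.  ``n_phos`` defaults to the copy number of a
    1e-7 M phosphatase concentration in the analytic cytoplasm volume.
    """
    net = mapk_network(use_effective_first_order=use_effective_first_order)
    geom = CellGeometry(cell_diameter, nucleus_diameter)
    init = [("MAPKpp", n_mapk, "membrane")]
    if not use_effective_first_order:
        if n_phos is None:
            n_phos = concentration_to_count(phos_concentration, geom.cytoplasm_volume)
        init.append(("P", n_phos, "cytoplasm"))
    if mode == "surfaces":
        mode_spec = ("surfaces", ["MAPKpp", "MAPK"])
    elif mode in ("particle", "population"):
        if mode == "particle" and not use_effective_first_order:
            mode_spec = ("species", ["MAPKpp", "MAPK"])  # phosphatase stays population
        else:
            mode_spec = mode
    else:
        mode_spec = mode
    cfg = SimulationConfig(
        cell_diameter=cell_diameter, nucleus_diameter=nucleus_diameter,
        grid_l=L, dt=dt, t_end=t_end, seed=seed, mode=mode_spec, init=init,
        record_interval=record_interval,
    )
    return run_simulation(net, cfg)


def scenario_crowding(phi_target: float, level: str = "population", *,
                      n_voxels: int = 20, l: float = 0.25, diffusion: float = 10.0,
                      n_walkers: int = 4000, t_max: float = 0.05, n_frames: int = 10,
                      dt: float = 1e-5, blob_radius: float | None = None,
                      uniform: bool = False, seed: int = 0) -> float:
    """Effective diffusion through a crowded periodic volume.

    Voxel-scale obstacles (random impenetrable blobs) produce tortuous paths
    and ``D_eff < D_0``; with ``uniform=True`` the same free-volume fraction
    is instead smeared homogeneously below the voxel scale, where it cancels
    from the jump rates and diffusion is unchanged.  Returns D_eff / D_0.
    """
    shape = (n_voxels,) * 3
    base = box_lattice(shape, l, periodic=True)
    if phi_target >= 1.0:
        om = None
    elif uniform:
        om = ObstacleMap.uniform(shape, phi_target)
    else:
        if blob_radius is None:
            blob_radius = 0.6 * l  # blocks roughly one voxel per blob
        om = generate_obstacle_map(base, phi_target, blob_radius, seed=seed + 7)
    lattice = box_lattice(shape, l, obstacles=om, periodic=True)
    rec_times = np.linspace(t_max / n_frames, t_max, n_frames)
    if level == "population":
        times, pos, _ = run_lattice_tracers(lattice, diffusion, n_walkers, rec_times, seed)
        return estimate_effective_diffusion(times, pos, diffusion)
    if level == "particle":
        times, traj = run_box_walkers(lattice, diffusion, n_walkers, dt, rec_times, seed)
        return estimate_effective_diffusion(times, traj, diffusion)
    raise ValueError("level must be 'population' or 'particle'")
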