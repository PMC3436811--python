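"""Validation suite: the statistical checks that certify the hybrid coupling.

Each function runs a self-contained experiment (independent of any stored
results) and returns plain numbers: analytic effective rates, a fitted
import rate, cross-mode agreement statistics for the annihilation test
case, equivalence tests between per-particle and population-level
first-order scheduling, residual-time distribution checks for the
propensity-stretching rule, conversion-invariance checks, crowding ratios
and single-volume cross-checks against an independent direct-method SSA
and mass-action ODEs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats

from .bridge import ModeMap
from .geometry import CellGeometry, box_lattice, discretize_cell
from .gillespie import GillespieEngine, draw_waiting_time, rescale_after_change
from .model import ReactionNetwork, ReactionSpec, SpeciesSpec
from .scenarios import scenario_ab_annihilation, scenario_crowding
from .simulate import HybridSimulation, SimulationConfig, run_simulation


# -- effective rates ----------------------------------------------------------


def nuclear_import_rate_analytic(cell_diameter: float = 10.0,
                                 nucleus_diameter: float = 3.0,
                                 permeability: float = 1.8) -> float:
    """Volumetric first-order import rate k_s A_nuc / V_cyt, s^-1."""
    geom = CellGeometry(cell_diameter, nucleus_diameter)
    return geom.nuclear_import_rate(permeability)


def dephosphorylation_rate_effective(k_p: float = 1e7, conc: float = 1e-7) -> float:
    """Pseudo-first-order rate k_p [P], s^-1."""
    return k_p * conc


def fit_nuclear_import_rate(seed: int, n_walkers: int = 10000, t_end: float = 2.0,
                            diffusion: float = 100.0, permeability: float = 1.8,
                            dt: float = 2.6e-5, grid_l: int = 10) -> float:
    """Fit the uptake of noninteracting walkers to a first-order rate.

    The walkers run in the reaction-limited regime (permeability well below
    the diffusive encounter limit), where the volumetric rate
    k_s A_nuc / V_cyt is the true uptake rate; the log-survival curve is fit
    through the origin.
    """
    net = ReactionNetwork(
        [SpeciesSpec("W", diffusion, 0.005, nuclear_capable=True)],
        [ReactionSpec(("W",), ("W",), permeability, kind="surface_transfer",
                      surface="nucleus")],
    )
    cfg = SimulationConfig(
        cell_diameter=10.0, nucleus_diameter=3.0, grid_l=grid_l, dt=dt,
        t_end=t_end, seed=seed, mode="particle",
        init=[("W", n_walkers, "cytoplasm")], record_interval=t_end / 10,
    )
    rec = run_simulation(net, cfg)
    surv = 1.0 - rec.nucleus_pool[:, 0] / n_walkers
    t = rec.times
    mask = t > 0
    return float(-np.sum(np.log(surv[mask]) * t[mask]) / np.sum(t[mask] ** 2))


# -- annihilation test case: cross-mode agreement -----------------------------


def ab_mode_agreement(seed: int, n_per_species: int = 2000, L: int = 10,
                      n_replicates: int = 20, k_on: float = 4e7,
                      dt: float = 1e-4, t_end: float = 1.0,
                      n_checkpoints: int = 10) -> dict:
    """Mean A(t) of the annihilation test case under the three level
    assignments, with pairwise deviations in units of the pooled SE.

    Returns ``{"means": {mode: (T,)}, "max_z": float, "pairwise": {...}}``;
    ``max_z`` is the largest |mean difference| / pooled SE over all mode
    pairs and checkpoints.
    """
    acc = {m: [] for m in ("particle", "population", "hybrid")}
    for rep in range(n_replicates):
        recs = scenario_ab_annihilation(
            n_per_species=n_per_species, L=L, seed=seed * 100003 + rep,
            k_on=k_on, dt=dt, t_end=t_end,
            record_interval=t_end / n_checkpoints,
        )
        for m, r in recs.items():
            acc[m].append(r.totals()[:, 0])
    arr = {m: np.asarray(v, dtype=float) for m, v in acc.items()}
    pairwise = {}
    max_z = 0.0
    for m1, m2 in itertools.combinations(arr, 2):
        a, b = arr[m1], arr[m2]
        se = np.sqrt(a.var(0, ddof=1) / n_replicates + b.var(0, ddof=1) / n_replicates)
        z = np.abs(a.mean(0) - b.mean(0)) / np.where(se > 0, se, np.inf)
        zmax = float(z[1:].max())  # t=0 shares the same initial count
        pairwise[(m1, m2)] = zmax
        max_z = max(max_z, zmax)
    return {"means": {m: arr[m].mean(0) for m in arr},
            "pairwise": pairwise, "max_z": max_z}


# -- first-order scheduling equivalence --------------------------------------


def first_order_equivalence(seed: int, n_events: int = 10000, n_molecules: int = 50,
                            k1: float = 2.0) -> dict:
    """Per-particle minimum-of-N scheduling vs one aggregate draw.

    The earliest of N per-molecule Exp(k) times is Exp(N k); the two
    scheduling schemes must give statistically identical first-event times
    (two-sample KS).  Also checks that the selected channel frequencies
    match a_i/a_0 for rates (1, 2, 3) (chi-square).
    """
    rng = np.random.default_rng(seed)
    per_particle = rng.exponential(1.0 / k1, size=(n_events, n_molecules)).min(axis=1)
    aggregate = rng.exponential(1.0 / (n_molecules * k1), size=n_events)
    ks = stats.ks_2samp(per_particle, aggregate)

    rates = np.array([1.0, 2.0, 3.0])
    net = ReactionNetwork(
        [SpeciesSpec("A"), SpeciesSpec("B1"), SpeciesSpec("B2"), SpeciesSpec("B3")],
        [ReactionSpec(("A",), (f"B{i+1}",), r) for i, r in enumerate(rates)],
    )
    n_draws = 100000
    chosen = np.array([
        rates.tolist().index(net.select_first_order_channel("A", rng).rate_constant)
        for _ in range(n_draws)
    ])
    observed = np.bincount(chosen, minlength=3)
    chi2 = stats.chisquare(observed, n_draws * rates / rates.sum())
    return {"ks_p": float(ks.pvalue), "chi2_p": float(chi2.pvalue)}


def channel_selection_by_propensity(seed: int, n_trials: int = 100000) -> float:
    """P(channel with propensity a_i fires first) must equal a_i/a_0.

    Stored next-event times are independent exponentials; the argmin over
    channels is multinomial with weights a_i/a_0 (chi-square p-value).
    """
    rng = np.random.default_rng(seed)
    a = np.array([0.5, 1.5, 3.0, 5.0])
    times = rng.exponential(1.0 / a, size=(n_trials, len(a)))
    winners = np.bincount(times.argmin(axis=1), minlength=len(a))
    return float(stats.chisquare(winners, n_trials * a / a.sum()).pvalue)


# -- propensity stretching ----------------------------------------------------


def rescaling_residual_ks(seed: int, n: int = 10000, a_old: float = 1.0,
                          a_new: float = 3.0, t_change: float = 0.7) -> float:
    """Residual times after stretching must be Exp(a_new) (one-sample KS).

    Times drawn at 0 with propensity a_old that survive past ``t_change``
    are stretched by a_old/a_new; their residuals beyond t_change must be
    exactly Exp(a_new).
    """
    rng = np.random.default_rng(seed)
    residuals = np.empty(n)
    got = 0
    while got < n:
        t0 = draw_waiting_time(a_old, rng)
        if t0 <= t_change:
            continue
        t_new = rescale_after_change(t_change, t0, a_old, a_new)
        residuals[got] = t_new - t_change
        got += 1
    return float(stats.kstest(residuals, "expon", args=(0, 1.0 / a_new)).pvalue)


# -- conversion invariance ----------------------------------------------------


def _decay_event_times(seed: int, n_replicates: int, n0: int, k1: float,
                       variant: str, t_end: float = 3.0, dt: float = 0.05,
                       grid_l: int = 3, threshold: int = 8) -> np.ndarray:
    """Pooled molecule death times of a decaying, diffusing species.

    Each molecule dies at an iid Exp(k1) time regardless of diffusion or of
    how often the representation switches level, so the pooled death times
    of any unbiased variant are Exp(k1) samples.  Death times are read off
    the recorded survival curve at dt resolution (midpoint of the step).
    """
    net = ReactionNetwork([SpeciesSpec("A", 5.0, 0.005)],
                          [ReactionSpec(("A",), (), k1)])
    out = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            cell_diameter=4.0, nucleus_diameter=0.0, grid_l=grid_l, dt=dt,
            t_end=t_end, seed=seed * 99991 + rep,
            mode="population" if variant != "particle_start" else "particle",
            init=[("A", n0, "cytoplasm")], record_interval=dt,
            convert_every=10 if variant == "flip" else 0,
            controller_threshold=threshold if variant == "controller" else 0,
            controller_interval=10,
        )
        rec = run_simulation(net, cfg)
        totals = rec.totals()[:, 0]
        deaths = -np.diff(totals)
        mids = 0.5 * (rec.times[1:] + rec.times[:-1])
        out.extend(np.repeat(mids, deaths.astype(int)))
    return np.asarray(out)


def conversion_invariance(seed: int, n_replicates: int = 1000, n0: int = 20,
                          k1: float = 1.0) -> dict:
    """Decay statistics with (a) no conversions, (b) full level flips every
    10 steps, (c) controller-driven switching: pairwise two-sample KS
    p-values of the pooled event times, plus KS against the exact Exp(k1)."""
    t_end, dt = 3.0, 0.05
    base = _decay_event_times(seed, n_replicates, n0, k1, "none", t_end, dt)
    flip = _decay_event_times(seed + 1, n_replicates, n0, k1, "flip", t_end, dt)
    ctrl = _decay_event_times(seed + 2, n_replicates, n0, k1, "controller", t_end, dt)
    # event times are known at dt resolution, so the exactness check is a
    # chi-square against the binned Exp(k1) probabilities (censored tail
    # pooled into the survival mass)
    edges = np.arange(0.0, t_end + dt / 2, dt)
    expected_p = np.diff(-np.exp(-k1 * edges))
    expected_p = np.append(expected_p, math.exp(-k1 * t_end))

    def chi2_exact(sample, n_total):
        obs = np.histogram(sample, bins=edges)[0]
        obs = np.append(obs, n_total - obs.sum())
        exp = expected_p * n_total
        keep = exp > 5
        obs_k, exp_k = obs[keep], exp[keep]
        if (~keep).any():
            obs_k = np.append(obs_k, obs[~keep].sum())
            exp_k = np.append(exp_k, exp[~keep].sum())
        return float(stats.chisquare(obs_k, exp_k * obs_k.sum() / exp_k.sum()).pvalue)

    return {
        "ks_p_flip": float(stats.ks_2samp(base, flip).pvalue),
        "ks_p_controller": float(stats.ks_2samp(base, ctrl).pvalue),
        "chi2_p_exact": chi2_exact(base, n_replicates * n0),
    }


# -- crowding -----------------------------------------------------------------


def crowding_suite(seed: int, level: str = "population") -> dict:
    """Uniform-phi cancellation and monotone slowdown with obstacle density."""
    uniform = scenario_crowding(0.6, level=level, uniform=True, seed=seed)
    ratios = {phi: scenario_crowding(phi, level=level, seed=seed)
              for phi in (1.0, 0.85, 0.7)}
    return {"uniform_phi_ratio": uniform, "ratios": ratios}


# -- independent oracles ------------------------------------------------------


def direct_ssa_ab(seed: int, n0: int, k_pair: float, t_end: float,
                  n_replicates: int = 64) -> float:
    """Mean A(t_end) of A + B -> 0 by the plain direct method.

    Deliberately naive and separate from the event-driven engine: propensity
    a = k_pair * nA * nB, waiting times Exp(a), no stored times, no lattice.
    """
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_replicates):
        na = nb = n0
        t = 0.0
        while na > 0:
            a = k_pair * na * nb
            t += rng.exponential(1.0 / a)
            if t > t_end:
                break
            na -= 1
            nb -= 1
        total += na
    return total / n_replicates


def ssa_cross_checks(seed: int, n0: int = 1000, k_on: float = 1e8,
                     t_end: float = 1.0, n_replicates: int = 32) -> dict:
    """Single-volume A+B->0: engine vs direct-method SSA vs mass-action ODE.

    Returns relative errors of the engine mean against both oracles and the
    Monte-Carlo standard error, all at t_end.
    """
    geom = CellGeometry(4.0, 0.0)
    lattice = discretize_cell(geom, 1)
    net = ReactionNetwork(
        [SpeciesSpec("A", 1.0, 0.01), SpeciesSpec("B", 1.0, 0.01)],
        [ReactionSpec(("A", "B"), (), k_on)],
    )
    k_pair = float(net.r2_kvol[0] / lattice.free_volume[0])
    rng = np.random.default_rng(seed)
    finals = []
    for _ in range(n_replicates):
        eng = GillespieEngine(net, lattice)
        eng.seed(int(rng.integers(2**31 - 1)))
        eng.counts[0, :] = n0
        eng.initialize()
        eng.advance_until(t_end)
        finals.append(eng.counts[0, 0])
    engine_mean = float(np.mean(finals))
    engine_se = float(np.std(finals, ddof=1) / math.sqrt(n_replicates))
    oracle = direct_ssa_ab(seed + 1, n0, k_pair, t_end, n_replicates=4 * n_replicates)
    sol = integrate.solve_ivp(lambda t, y: [-k_pair * y[0] * y[0]], [0, t_end],
                              [float(n0)], t_eval=[t_end], rtol=1e-10)
    ode = float(sol.y[0, -1])
    return {
        "engine_mean": engine_mean, "engine_se": engine_se,
        "direct_ssa_mean": oracle, "ode": ode,
        "rel_err_vs_ssa": abs(engine_mean - oracle) / oracle,
        "rel_err_vs_ode": abs(engine_mean - ode) / ode,
    }


def wellmixed_particle_vs_ode(seed: int, n0: int = 2000, k_on: float = 1e8,
                              t_end: float = 0.4, dt: float = 5e-5,
                              n_replicates: int = 10, hybrid: bool = False) -> dict:
    """Well-mixed A+B->0 far below the diffusion limit: collision-driven
    particle kinetics (or the cross-level quasi-first-order scheme when
    ``hybrid``) must match the mass-action ODE."""
    net = ReactionNetwork(
        [SpeciesSpec("A", 10.0, 0.01), SpeciesSpec("B", 10.0, 0.01)],
        [ReactionSpec(("A", "B"), (), k_on)],
    )
    geom = CellGeometry(4.0, 0.0)
    finals = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            cell_diameter=4.0, nucleus_diameter=0.0, grid_l=2, dt=dt,
            t_end=t_end, seed=seed * 7919 + rep,
            mode=("species", ["A"]) if hybrid else "particle",
            init=[("A", n0, "cytoplasm"), ("B", n0, "cytoplasm")],
            record_interval=t_end,
        )
        rec = run_simulation(net, cfg)
        finals.append(rec.totals()[-1, 0])
    k_pair = float(net.r2_kvol[0] / geom.cytoplasm_volume)
    sol = integrate.solve_ivp(lambda t, y: [-k_pair * y[0] * y[0]], [0, t_end],
                              [float(n0)], t_eval=[t_end], rtol=1e-10)
    ode = float(sol.y[0, -1])
    mean = float(np.mean(finals))
    return {"mean": mean, "ode": ode, "rel_err": abs(mean - ode) / ode,
            "se": float(np.std(finals, ddof=1) / math.sqrt(n_replicates))}
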