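"""Reaction-network model: species, reaction channels and rate-unit algebra.

All internal quantities use micrometres, seconds and cubic micrometres.
Molar rate constants and concentrations are converted once, when a model is
built, using a fixed Avogadro constant; every engine downstream consumes
rates in s^-1 (first order), um^3/s per reactant pair (second order) or
um/s (surface transfer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214e23

#: Litres per cubic micrometre.
LITER_PER_UM3 = 1e-15

#: Copy numbers per um^3 at a concentration of 1 M.
COUNTS_PER_UM3_PER_MOLAR = N_AVOGADRO * LITER_PER_UM3


class ModelError(ValueError):
    """Raised for an invalid species/reaction definition."""


def bimolecular_rate_to_sim_units(k: float, v_free: float) -> float:
    """Convert a bimolecular rate constant to a per-pair propensity.

    Parameters
    ----------
    k
        Rate constant in M^-1 s^-1.
    v_free
        Accessible (free) volume in um^3 in which the reactant pair mixes.

    Returns
    -------
    float
        Propensity factor in s^-1 for one reactant pair confined to
        ``v_free``: ``k / (N_A * v_free * 1e-15)``.
    """
    if v_free <= 0:
        raise ModelError(f"degenerate subvolume: free volume {v_free} um^3 must be positive")
    return k / (N_AVOGADRO * v_free * LITER_PER_UM3)


def bimolecular_rate_to_volume_rate(k: float) -> float:
    """Convert k in M^-1 s^-1 to a pair-encounter volume rate in um^3/s."""
    return k / (N_AVOGADRO * LITER_PER_UM3)


def concentration_to_count(c: float, v: float) -> int:
    """Copy number of a species at concentration ``c`` (M) in volume ``v`` (um^3)."""
    if c < 0:
        raise ModelError("concentration must be nonnegative")
    if v <= 0:
        raise ModelError("volume must be positive")
    return int(round(c * N_AVOGADRO * v * LITER_PER_UM3))


def count_to_concentration(n: int, v: float) -> float:
    """Concentration in M of ``n`` copies in volume ``v`` (um^3)."""
    if v <= 0:
        raise ModelError("volume must be positive")
    return n / (N_AVOGADRO * v * LITER_PER_UM3)


def diffusion_limit_check(k: float, sigma: float, d_sum: float, *, threshold: float = 0.1):
    """Compare a bimolecular rate constant against the Smoluchowski limit.

    Molecules cannot react faster than the rate at which diffusion brings
    them together, ``k_D = 4 pi sigma D`` with ``D`` the summed diffusion
    coefficients of the pair.  Rates approaching ``k_D`` are flagged so the
    caller can warn that a population-level treatment will underestimate the
    true rate (no abort: the simulation stays valid, only less accurate).

    Returns ``(status, k_d_molar)`` where status is ``"ok"`` or
    ``"diffusion_limited"`` and ``k_d_molar`` is the limit in M^-1 s^-1.
    """
    if sigma <= 0 or d_sum <= 0:
        raise ModelError("collision radius and diffusion sum must be positive")
    k_d_volume = 4.0 * math.pi * sigma * d_sum  # um^3/s
    k_d_molar = k_d_volume * N_AVOGADRO * LITER_PER_UM3
    status = "diffusion_limited" if k > threshold * k_d_molar else "ok"
    return status, k_d_molar


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species.

    ``diffusion`` is the free-space diffusion coefficient in um^2/s and
    ``radius`` the interaction radius in um (collision radius of a pair is
    the sum of the two radii).  ``nuclear_capable`` marks species that may
    cross the nuclear envelope; ``membrane_bound`` marks species living on
    the plasma membrane rather than in the cytoplasm.
    """

    name: str
    diffusion: float = 0.0
    radius: float = 0.0
    nuclear_capable: bool = False
    membrane_bound: bool = False

    def __post_init__(self):
        if self.diffusion < 0:
            raise ModelError(f"species {self.name}: diffusion coefficient must be >= 0")
        if self.radius < 0:
            raise ModelError(f"species {self.name}: radius must be >= 0")


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction channel.

    order 1: ``A -> products`` with rate constant in s^-1.
    order 2: ``A + B -> products`` with rate constant in M^-1 s^-1
    (Michaelis-Menten style catalysis is an order-2 channel whose enzyme
    appears in both reactants and products, ``catalytic=True``).
    ``surface_transfer``: adsorption of a single bulk reactant onto the
    nuclear envelope or plasma membrane with a permeability in um/s.
    """

    reactants: tuple
    products: tuple
    rate_constant: float
    order: int = 0
    kind: str = "bulk"  # "bulk" | "surface_transfer"
    surface: str | None = None  # "nucleus" | "membrane" for surface_transfer
    catalytic: bool = False
    name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if self.order == 0:
            object.__setattr__(self, "order", len(self.reactants))
        if self.rate_constant < 0:
            raise ModelError("rate constant must be >= 0")
        if self.kind == "surface_transfer":
            if len(self.reactants) != 1:
                raise ModelError("surface_transfer needs exactly one bulk reactant")
            if self.surface not in ("nucleus", "membrane"):
                raise ModelError("surface_transfer must name surface 'nucleus' or 'membrane'")
        elif self.kind == "bulk":
            if self.order not in (1, 2):
                raise ModelError("only order-1 and order-2 bulk reactions are supported")
            if len(self.reactants) != self.order:
                raise ModelError("reactant list length must equal the reaction order")
            if self.catalytic:
                enzymes = set(self.reactants) & set(self.products)
                if not enzymes:
                    raise ModelError("catalytic reaction must list the enzyme in reactants and products")
        else:
            raise ModelError(f"unknown reaction kind {self.kind!r}")


class ReactionNetwork:
    """Validated species + reaction channels with unit-normalised rates.

    Exposes the arrays the simulation engines consume:

    - ``k1_aggregate[i]``: summed first-order rate constants of species i
      (s^-1); species without a first-order channel get 0 and an infinite
      waiting time downstream.
    - per-species first-order channel tables (rates and stoichiometry rows),
    - order-2 channel tables with per-pair volume rates in um^3/s,
    - surface-transfer channel tables with permeabilities in um/s.
    """

    def __init__(self, species, reactions):
        self.species = list(species)
        self.reactions = list(reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("species names must be unique")
        self.index = {name: i for i, name in enumerate(names)}
        self.n_species = len(names)
        for r in self.reactions:
            for name in (*r.reactants, *r.products):
                if name not in self.index:
                    raise ModelError(f"reaction references unknown species {name!r}")

        m = self.n_species
        self.diffusion = np.array([s.diffusion for s in self.species])
        self.radius = np.array([s.radius for s in self.species])
        self.nuclear_capable = np.array([s.nuclear_capable for s in self.species])

        # --- first-order channels, grouped by reactant species -----------
        self.first_order = [[] for _ in range(m)]
        for r in self.reactions:
            if r.kind == "bulk" and r.order == 1:
                self.first_order[self.index[r.reactants[0]]].append(r)
        self.k1_aggregate = np.array(
            [sum(r.rate_constant for r in chans) for chans in self.first_order]
        )
        # flattened tables for the compiled kernels
        self.fo_offsets = np.zeros(m + 1, dtype=np.int64)
        fo_rate, fo_delta = [], []
        for i, chans in enumerate(self.first_order):
            self.fo_offsets[i + 1] = self.fo_offsets[i] + len(chans)
            for r in chans:
                fo_rate.append(r.rate_constant)
                fo_delta.append(self.stoich_delta(r))
        self.fo_rate = np.array(fo_rate, dtype=np.float64)
        self.fo_delta = (
            np.array(fo_delta, dtype=np.int64) if fo_delta else np.zeros((0, m), dtype=np.int64)
        )

        # --- order-2 channels --------------------------------------------
        self.bimolecular = [r for r in self.reactions if r.kind == "bulk" and r.order == 2]
        self.r2_a = np.array([self.index[r.reactants[0]] for r in self.bimolecular], dtype=np.int64)
        self.r2_b = np.array([self.index[r.reactants[1]] for r in self.bimolecular], dtype=np.int64)
        self.r2_kvol = np.array(
            [bimolecular_rate_to_volume_rate(r.rate_constant) for r in self.bimolecular]
        )
        self.r2_delta = (
            np.array([self.stoich_delta(r) for r in self.bimolecular], dtype=np.int64)
            if self.bimolecular
            else np.zeros((0, m), dtype=np.int64)
        )

        # --- surface transfer channels ------------------------------------
        self.surface_transfers = [r for r in self.reactions if r.kind == "surface_transfer"]
        self.rs_species = np.array(
            [self.index[r.reactants[0]] for r in self.surface_transfers], dtype=np.int64
        )
        self.rs_k = np.array([r.rate_constant for r in self.surface_transfers])
        self.rs_nucleus = np.array([r.surface == "nucleus" for r in self.surface_transfers])

        # collision radii sigma_ij = r_i + r_j for reactive pairs only
        self.sigma = np.full((m, m), -1.0)
        self.pair_channel = np.full((m, m), -1, dtype=np.int64)
        for ch, r in enumerate(self.bimolecular):
            ia, ib = self.index[r.reactants[0]], self.index[r.reactants[1]]
            sig = self.radius[ia] + self.radius[ib]
            self.sigma[ia, ib] = self.sigma[ib, ia] = sig
            self.pair_channel[ia, ib] = self.pair_channel[ib, ia] = ch

    # -- helpers ------------------------------------------------------------

    @property
    def n_bimolecular(self) -> int:
        return len(self.bimolecular)

    @property
    def n_surface(self) -> int:
        return len(self.surface_transfers)

    def species_index(self, name: str) -> int:
        return self.index[name]

    def stoich_delta(self, reaction: ReactionSpec) -> np.ndarray:
        """Net copy-number change per species when ``reaction`` fires once."""
        delta = np.zeros(self.n_species, dtype=np.int64)
        for name in reaction.reactants:
            delta[self.index[name]] -= 1
        for name in reaction.products:
            delta[self.index[name]] += 1
        return delta

    def select_first_order_channel(self, species, rng) -> ReactionSpec:
        """Draw the concrete first-order channel for a firing of ``species``.

        Channel i is chosen with probability ``k_i / k1_aggregate``; only the
        aggregate waiting time is scheduled, the channel identity is resolved
        at firing time.
        """
        i = species if isinstance(species, (int, np.integer)) else self.index[species]
        chans = self.first_order[i]
        agg = self.k1_aggregate[i]
        if not chans or agg <= 0:
            raise ModelError(
                f"species {self.species[i].name!r} has no first-order channel to select"
            )
        if len(chans) == 1:
            return chans[0]
        probs = np.array([r.rate_constant for r in chans]) / agg
        return chans[rng.choice(len(chans), p=probs)]

    def check_diffusion_limits(self, *, threshold: float = 0.1):
        """Flag bimolecular channels whose rate approaches the encounter limit.

        Returns a list of ``(reaction, status, k_D in M^-1 s^-1)``; channels
        with zero collision radius or immobile pairs are skipped.
        """
        out = []
        for r in self.bimolecular:
            ia, ib = self.index[r.reactants[0]], self.index[r.reactants[1]]
            sigma = self.radius[ia] + self.radius[ib]
            d_sum = self.diffusion[ia] + self.diffusion[ib]
            if sigma <= 0 or d_sum <= 0:
                continue
            status, k_d = diffusion_limit_check(r.rate_constant, sigma, d_sum, threshold=threshold)
            out.append((r, status, k_d))
        return out


# -- model description files -------------------------------------------------


def network_from_dict(doc: dict) -> ReactionNetwork:
    """Build a :class:`ReactionNetwork` from a parsed model document.

    The document has a ``species`` list (name, D, radius, flags) and a
    ``reactions`` list (reactants, products, rate, kind, surface, catalytic);
    see the README for the full schema.
    """
    species = [
        SpeciesSpec(
            name=s["name"],
            diffusion=float(s.get("D", 0.0)),
            radius=float(s.get("radius", 0.0)),
            nuclear_capable=bool(s.get("nuclear_capable", False)),
            membrane_bound=bool(s.get("membrane_bound", False)),
        )
        for s in doc.get("species", [])
    ]
    reactions = [
        ReactionSpec(
            reactants=tuple(r.get("reactants", [])),
            products=tuple(r.get("products", [])),
            rate_constant=float(r["rate"]),
            kind=r.get("kind", "bulk"),
            surface=r.get("surface"),
            catalytic=bool(r.get("catalytic", False)),
            name=r.get("name"),
        )
        for r in doc.get("reactions", [])
    ]
    return ReactionNetwork(species, reactions)


def load_model(path) -> ReactionNetwork:
    """Parse a model description file (YAML) into a ReactionNetwork."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return network_from_dict(doc)
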