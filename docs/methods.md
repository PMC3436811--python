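# Methods

`rdhybrid` simulates intracellular reaction–diffusion kinetics with two
coupled stochastic representations of the same chemistry: an event-driven
spatial Gillespie (next-reaction) engine operating on population counts in
cubic lattice subvolumes, and a fixed-timestep Brownian-dynamics engine
tracking individual molecules.  Any (subvolume, species) slot can be
assigned to either level, and the assignment can change during a run.  The
point of the coupling rules below is that the switch is *statistically
silent*: waiting-time statistics are preserved across conversions without
re-randomisation, so frequent switching does not bias reaction rates.

## Geometry and lattice

The compartment is a spherical cell (diameter `d`, default 10 µm) with an
optional concentric spherical nucleus (default 3 µm).  The bounding box is
divided into `L` cubic subvolumes per axis (`l = d/L`).  A cube is an
active subvolume iff its clipped overlap volume with the cytoplasm is
positive; overlap volumes and interface areas of boundary cubes are
computed by subsampling (10³ points per cube, 10² per face; coarse
lattices with `L < 4` get proportionally finer sampling).  Sliver cubes
with `V < 10⁻⁶ l³` are merged into their largest neighbour to avoid
near-zero-volume propensity blow-ups.  The total clipped volume matches
the analytic cytoplasm volume to ≲0.1 % at `L = 10`.

Sphere-surface areas (nuclear envelope, plasma membrane) are apportioned
to the cubes they cross with a deterministic Fibonacci-lattice covering of
10⁵ surface points; the per-cube areas sum to `4πr²` exactly up to the
covering resolution.

Published subvolume totals for this kind of discretisation depend strongly
on the membership convention (whether cubes merely touching the sphere
count, grid alignment, halo layers).  Under the positive-overlap
convention used here, `L = 10/20/30` give `U = 720/4984/15920`.  We treat
`U` as a derived quantity, validated against a brute-force enumeration
oracle, and do not match any particular printed total.

A separate constructor builds uniform box lattices (optionally periodic)
for free-diffusion and crowding studies where membrane curvature is
irrelevant.

## Population level (spatial next-reaction method)

Each subvolume ν stores `2M + R₂ + R_s` absolute next-event times:

- one *aggregated first-order time* per species (slot `i < M`): the
  minimum pending first-order reaction time over the `N_i` molecules of
  species `i` in ν;
- one diffusion-jump time per species (propensity `N_i · D_i · Σ_faces g`);
- one time per bimolecular channel (`k/(N_A·V_free·10⁻¹⁵) · N_A N_B`, or
  `N(N−1)/2` for identical reactants);
- one time per surface-transfer channel (`N_i · k_s S_surf(ν) / V_ν`).

An indexed binary min-heap over per-volume minima yields the global next
event; ties break by volume index.  After any state change, jump, reaction
and surface slots are *stretched*: `t_new = t + (a_old/a_new)(t_old − t)`,
with fresh draws only when a channel switches on from zero propensity.
By the memorylessness of the exponential this reproduces the exact
process while reusing the stored randomness.

The diffusion jump rate from ν to a face neighbour µ is

    k(ν→µ) = D · S_νµ · φ_edge / (V_ν · φ_ν · l),

which is `D/l²` for interior uncrowded cubes.  The firing molecule's
destination is drawn among open faces in proportion to their geometric
factors; this preserves the aggregate per-species jump rate while storing
only one jump time per species (the destination distribution is
exchangeable across the molecules of a species).

### First-order bookkeeping (the carry rules)

The aggregated first-order time per species is *not* rescheduled by
stretching.  Conditioned on the stored minimum `m`, a uniformly chosen
molecule holds `m` itself with probability `1/N`, and every other
molecule's time is `m + Exp(k₁)` by memorylessness — this holds even when
molecules entered the volume at different times, because the argmin of
exponentials with equal rate but different anchors is uniform given the
minimum value.  Hence:

- when a random molecule *leaves* (jump, consumption by a bimolecular or
  surface event): with probability `1/N` it carried the minimum, and the
  slot is redrawn as `m + Exp((N−1)k₁)`; otherwise the slot is unchanged
  and the leaver's own time is `m + Exp(k₁)`;
- a *jumping* molecule transfers its time into the destination volume by
  min-merge;
- when the stored minimum *fires*, the concrete channel is drawn with
  probabilities `k_i/k₁` and the slot is redrawn from the remaining
  aggregate anchored at the firing time;
- a *created* molecule min-merges a fresh `t + Exp(k₁)` draw.

All redraw anchors are the stored minimum, never the current clock: an
early version anchored at the current time and inflated first-order rates
by ~90 % in diffusion-dominated runs (each jump then injected an
unconditioned fresh draw below the stored minimum).  The m-anchored rules
reproduce `exp(−kt)` decay exactly in the presence of arbitrarily fast
diffusion (verified at z ≈ 0.5 over 2×10⁵ molecules).

## Particle level

Positions evolve by `x' = x + √(2 D Δt) ξ` with ξ standard normal.
Proposed moves into forbidden space — outside the cell, into the nucleus,
into an inaccessible voxel — are *rejected*: the molecule keeps its
position for that step (no reflection, no partial moves).  Rejection with
a symmetric proposal preserves the uniform equilibrium measure (verified
by χ² on the radial density).  Tracked molecules may overlap; excluded
volume between them is out of scope (signalling species are dilute).

Each particle carries its own next first-order reaction time, drawn from
the species aggregate `k₁` at creation; due events execute in time order
at each synchronisation point, with the concrete channel drawn at firing
time.

Bimolecular reactions are collision-driven: pairs with
`|x_a − x_b| < σ_ij = r_i + r_j` (strict) are found by a cell-list search
with bin edge `max σ`, and react with probability

    P = k_sim Δt / V_σ ,   k_sim = k/(N_A·10⁻¹⁵) µm³/s,  V_σ = (4/3)πσ³,

i.e. the pair is treated as well mixed within its collision sphere.  This
convention is validated against the mass-action ODE in the well-mixed,
reaction-limited regime (≤2 % at n₀ = 2000, 10 replicates); probabilities
above 1 are clipped with a warning to reduce Δt.  Candidate pairs are
processed in ascending id order; a molecule consumed by an earlier pair is
skipped, so each particle reacts at most once per step.  Products are
placed at the pair midpoint (first-order products at the reactant's
position).

Surface interactions convert a permeability `k_s` (µm/s) into a
per-crossing-attempt absorption probability `P = k_s √(πΔt/D)` (the
standard reactive-boundary conversion for fixed-step Brownian dynamics);
failures reject the step.  For the reference cell this reproduces the
volumetric import rate `k_s A_nuc / V_cyt = 0.0999 s⁻¹` to 0.6 % when the
permeability is small against the diffusive encounter rate.  With
`D = 10 µm²/s` the dimensionless permeability `k_s a/D = 0.27` is *not*
small, and the true long-time uptake rate is the diffusion-influenced
Collins–Kimball value `≈ 0.08 s⁻¹`; the import-rate validation therefore
runs its walkers at `D = 100 µm²/s`, where the reaction-limited value is
the correct answer.  This is a regime choice, not a calibration: at
`D = 10` the fitted rate measures a different physical quantity.

## Cross-level coupling

Level assignment is a per-(subvolume, species) mode map; every molecule is
represented at exactly one level (asserted in tests).  The rules:

- **particle → population conversion**: counts from the census; the
  species slot becomes the minimum of the particles' own times; jump and
  higher-order slots are freshly initialised (their stored propensity was
  zero); particles are deleted.
- **population → particle conversion**: `N` particles uniform over the
  subvolume; the first inherits the stored time `t_i`, the others get
  `t_i + Exp(k₁)` — exactly the conditional law of the order statistics
  given their minimum.  A single molecule therefore keeps its assigned
  time through arbitrarily many conversions.
- **jump into a particle-mode volume**: the created particle inherits the
  stored time with probability `1/N`, else `m + Exp(k₁)`; it is placed
  uniformly in a slab of depth `min(l/10, √(2DΔt))` behind the shared
  face, preserving flux directionality.
- **particle walks into a population-mode volume**: the crossing is
  accepted with probability `√(πDΔt)/l` — the level interface acts as a
  partially absorbing boundary with permeability `D/l`, the lattice
  exchange velocity — and otherwise the step is rejected.  On acceptance
  the count is incremented and the stored time min-merged with the
  particle's own time.  Unconditional conversion on first touch would be
  flux-inconsistent: a walker's gross crossing rate `√(D/(πΔt))` exceeds
  the lattice's re-emission velocity `D/l` by an order of magnitude at
  typical resolutions, draining particle zones into population zones
  (observed as a ~5× uptake deficit in the hybrid import scenario before
  the correction).  With the acceptance rule, gross fluxes balance at
  equal densities and the hybrid uptake curve matches the all-particle
  run.
- **cross-level bimolecular reaction**: a particle of species `i` in a
  volume holding `N_j` population partners reacts per step with
  probability `1 − exp(−k_ij N_j/V_ν · Δt)` (pseudo-first-order collapse
  of the mass-action rate); one partner is then removed by the carry
  rules.
- **controller**: optional automated switching — population slots below a
  count threshold convert to particles, particle slots at ≥ 2× threshold
  convert back; the hysteresis factor 2 prevents flapping at the
  threshold.

## Master loop

One global step Δt: (1) Brownian moves with boundary handling and level
crossings; (2) particle–particle collision reactions, then cross-level
attempts; (3) due per-particle first-order events in time order; (4) the
population engine advances event-driven to the synchronisation point
(jumps into particle volumes surface as callbacks).  The order is fixed
for reproducibility.  Runs with no particles and no switching bypass the
Δt loop entirely and advance the event-driven engine per record interval.

Randomness comes from two streams seeded from the run seed: a numpy
generator for particle-level draws and placement, and the compiled
(numba) stream for the event engine and carry decisions.  A fixed seed
gives bit-identical trajectories.

## Crowding

Crowding enters as per-voxel free-volume fractions φ ∈ [0, 1].  Node
factors rescale `V → Vφ` (raising effective concentrations, hence
bimolecular propensities) and face factors rescale `S → S φ_edge`.  The
edge fraction is 0 if either voxel is inaccessible, else the mean of the
two node fractions — exact in both limits the theory distinguishes:
homogeneous sub-voxel crowding (φ cancels from the jump rate; verified
`D_eff/D₀ = 1` exactly) and voxel-scale binary obstacles (binary edge
weights; tortuosity reduces `D_eff/D₀`, e.g. ≈ 0.6 at φ = 0.7).
The obstacle generator drops random impenetrable spheres until a target
free fraction is reached within 1 % — a synthetic stand-in for
microscopy-derived obstacle geometries, which also means published
effective-diffusion values for real geometries are not reproduction
targets; the package validates the cancellation identity and
monotonicity instead.  Effective diffusion is estimated from the
mean-square displacement of independent tracers (kinetic Monte Carlo on
the weighted lattice at the population level; Brownian walkers with voxel
rejection at the particle level), fit through the origin as `6 D_eff t`
over displacements of a few voxel lengths in a periodic box.

## Validation experiments and problem sizes

The shipped validation suite (also run by `scripts/acceptance.py`) uses:

- analytic rate identities (closed form);
- import-rate fit: 10⁴ walkers, 2 s, Δt = 2.6×10⁻⁵ s, `D = 100 µm²/s`;
- annihilation agreement: 2000 molecules per species (A released at the
  membrane, B at the nuclear surface), `L = 10`, `k = 4×10⁷ M⁻¹s⁻¹`
  (≈1 % of the diffusion limit for σ = 0.02 µm), Δt = 10⁻⁴ s, 1 s
  simulated, 20 replicates per mode, 10 checkpoints; the criterion is
  pairwise mean agreement within 3 pooled standard errors.  The original
  study used 20 000 molecules per species and longer runs; the scaled-down
  version keeps the segregated initial condition that makes the comparison
  hard;
- scheduling equivalence and stretching: 10⁴–10⁵ draws, KS/χ² at α=0.01;
- conversion invariance: 1000 replicates of 20 molecules decaying at
  1 s⁻¹ (Δt = 0.05 s, flips every 10 steps ≈ half a mean waiting time);
  pooled death times compared by two-sample KS, plus a binned χ² against
  the exact exponential;
- crowding: periodic 20³ box, `l = 0.25 µm`, 4000 tracers;
- oracle checks: an independently coded direct-method SSA (no stored
  times, no lattice) and `solve_ivp` mass-action ODEs.

What these runs do *not* probe: real obstacle microstructure, membrane
curvature effects on adsorption, crowding between tracked particles,
reactions faster than ~10 % of the diffusion limit (where the
population-level treatment underestimates rates and a finer-grained
correction would be needed — the simulator only warns), and nuclear
export (the nucleus is an absorbing pool).

## Degenerate inputs and numerical edges

Species with no first-order channel carry an infinite waiting-time
sentinel.  Zero-propensity slots hold ∞ and never fire.  Free volumes of
zero make a voxel inactive (no molecules may reside there).  Collision
probabilities and surface probabilities above 1 are clipped with logged
warnings.  Bimolecular channels faster than 10 % of `k_D = 4πσD` are
flagged `diffusion_limited` (logged, never fatal).  Event-time ties break
deterministically by volume index; collision pairs process in id order.
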