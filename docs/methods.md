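# Methods

## Model

The membrane is an L x L square lattice with periodic boundaries. Each
lipid site carries an Ising spin s = ±1; s = +1 denotes the ordered
(dark, liquid-ordered) phase, s = −1 the disordered (bright,
liquid-disordered) phase. The Hamiltonian is

    H = −J Σ_<ij> s_i s_j  −  J_int Σ_(b,l) b s_l

where the first sum runs over nearest-neighbour lipid–lipid bonds and the
second over pairs of an inclusion-boundary site (carrying the inclusion's
uniform boundary value b = ±1) and an adjacent lipid. J > 0 sets the
energy unit (default J = 1); J_int defaults to J and is configurable.
Temperature is specified as the rescaled temperature τ = T / Tc of the
*bare* lattice, Tc = 2J / ln(1 + √2) (Onsager). With inclusions present
the true critical point of the composite system sits at τ slightly above
1, increasingly so for larger and denser inclusions; all temperatures are
reported relative to the bare membrane.

Membrane composition is the magnetization m = ⟨s⟩ over lipid sites,
a proxy for the area-fraction imbalance of the two phases. The up-spin
count is round(n_lipid (1+m)/2); the simulation driver places inclusions
first and then assigns lipid spins, so the achieved m is exact over the
lipids actually present (it is also re-measured and recorded).

### Dynamics

* **Lipids** evolve by Kawasaki exchange: per sweep, n_lipid attempts,
  each picking a uniformly random lipid site and a uniformly random
  4-neighbour (null move if the neighbour is not a lipid) and exchanging
  the two spins with Metropolis probability min(1, exp(−ΔE/T)). The
  order parameter is conserved locally (model-B dynamics). Random site
  selection (not typewriter order) avoids directional bias.
* **Inclusions** are closed rasterized disks (footprint dx²+dy² ≤ r²);
  boundary sites are footprint sites with a 4-neighbour outside the
  footprint. r = 0 is a single site, r = 1 the 5-site plus shape whose
  centre is enclosed (it touches no lipid and carries no coupling).
  Per sweep each disk makes C (default 1 — proteins diffuse slower than
  lipids) one-site translation attempts in random directions, in
  randomised disk order. A move is rejected outright if the destination
  footprint overlaps another inclusion (hard-core exclusion is the only
  direct disk–disk interaction). Otherwise the lipid spins on the
  leading edge are relocated to the trailing edge in sorted-offset order
  — a deterministic bijection that is its own inverse under the reverse
  move, making the proposal symmetric — and the move is accepted with the
  Metropolis factor. Lipid composition is conserved exactly.
* **Reactions** run once per sweep after the movement phase: contacts are
  unordered inclusion pairs with 4-adjacent boundary sites; each contact
  matching a declared rule (actor species, target species, target in the
  required before-state) yields one Bernoulli trial at the rule's rate
  (default 0.1 per contact per sweep); candidates fire in random order
  and each target changes state at most once per sweep. A state change
  immediately and unconditionally resets the target's boundary value to
  its partitioning for the new state; because this does not depend on the
  surrounding lipid configuration, partition-switching networks violate
  detailed balance. With static partitioning the spatial ensemble remains
  exactly Boltzmann (internal states do not feed back on energies).

ΔE is tracked incrementally everywhere (swap-local sums for Kawasaki,
a fixed local box re-summation for disk moves, boundary-neighbour sums
for partition switches) and is exact in float64 for integer couplings;
a long-run test asserts bit-exact agreement with a from-scratch total.

### Equilibration aid

Kawasaki dynamics near τ = 1 suffer severe (model-B) critical
slowing-down: an L = 64 lattice takes well over 10⁶ sweeps to equilibrate
from a random start. `lattice.equilibrate_exchange` therefore provides
*nonlocal* spin exchange (two uniformly random lipid sites per attempt,
Metropolis). It has the same stationary Boltzmann law on the
fixed-magnetization class but mixes orders of magnitude faster, and it is
used only to prepare initial states, never as the model's dynamics.
Simulation configs expose `pre_equilibrate_sweeps`: before the reaction
phase, blocks of nonlocal exchange alternate with ordinary (reaction-free)
scheduler sweeps so both the solvent and the inclusion positions start
from a typical equilibrium configuration of the reaction-free system.
For static-partitioning networks that ensemble is exactly the stationary
spatial law; for partition-switching networks it is the all-inactive
equilibrium that the reactions then perturb.

## Observables and analysis

* **Activity** f_A = (active targets)/(targets), recorded every sweep;
  steady-state summaries discard a burn-in fraction (default 0.5).
* **Cross-correlations** g(r): histogram of minimum-image
  centre-to-centre distances between two species (bin width 1 lattice
  unit), averaged over snapshots and normalized by the exact lattice
  displacement census, so g ≡ 1 for ideal-gas placements.
* **Dark clusters and pockets**: dark sites are +1 lipids plus the whole
  footprint of any inclusion whose current boundary value is +1 (pockets
  are protein-rich, so footprints must count). Clusters are 4-connected
  with periodic wrap; clusters of ≥ min_size (default 10) sites are kept.
  A cluster is a *pocket* iff its occupant census (inclusions whose
  footprint intersects the cluster) has ≥ 1 active target, ≥ 1 activator
  (recruiter) and 0 inactivators (excluders).
* **Pocketed-run flag**: a replicate is flagged when its mean activity
  exceeds the across-replicate median by iqr_mult (default 0.5)
  interquartile ranges AND a pocket persists for at least min_persist
  (default 3) consecutive snapshots. Persistence is the physical
  evidence of a pocket; the activity clause rejects transient clusters
  that never matter kinetically. The defaults were calibrated on pilot
  runs of the partition-switching protocol so that replicates carrying a
  long-lived pocket are flagged while unremarkable replicates are not;
  both knobs are exposed.
* **Logistic fits**: f_A(τ) = (R−L)/2·tanh((τ−τ0)/(2Δτ)) + (R+L)/2 via
  Levenberg–Marquardt (scipy), initialized at L = min f, R = max f,
  τ0 at the steepest finite-difference slope, Δτ = span/4, with bounds
  keeping Δτ > 0. Optimizer failure or flat data yields converged=False,
  never an exception; 95% CIs come from the asymptotic covariance.
* **Sign rule**: each pathway carries (activity sign) × (contact-trend
  sign), the latter derived from partitioning (− if actor and pre-state
  target partition alike, + otherwise). If all pathway products agree the
  common sign predicts the slope of activity in τ; otherwise the rule is
  indeterminate.

## Study conditions (scaled-down defaults)

The validation protocols in `memppi.protocols` share rate 0.1,
J_int = J = 1, pre-equilibration before the reaction phase, and half the
measurement sweeps discarded as burn-in. The per-protocol conditions,
chosen once from physical considerations and pilot calibration:

* **Radius / growth-width protocol** (also supplies the τ-trend check on
  its r = 1 slice): L = 48, 4 activators / 4 inactivators / 8 targets
  matched across radii {0,1,2,3}, C = 1, 2000 pre-equilibration + 10000
  measurement sweeps, τ grid {0.85, 0.95, 1.05, 1.15, 1.3, 1.5}, 10
  replicates. Low counts keep even r = 3 disks at ~20% area so the
  critical-point shift stays moderate; the grid still extends to 1.5 to
  bracket the displaced large-radius transitions.
* **Composition (m) protocol**: L = 64, 4 activators / 8 inactivators /
  8 targets, τ = 1.1, C = 2, 6000 pre-equilibration + 16000 measurement
  sweeps, m ∈ {−0.4, 0, 0.4}, radii {0, 3}. The inactivator-rich
  composition matters: with as many targets as excluders, the scarce
  dark droplets at negative m often hold targets but no excluder, a
  discrete-number artifact that reverses the composition trend.
* **Pocketing protocol**: L = 64, 8 activators / 8 inactivators / 16
  targets of r = 2 (~10% area), C = 2, 2000 + 25000–40000 sweeps,
  m ∈ {0, −0.4}, τ below and above 1, ≥20 replicates at the m = 0 point.
  Pockets need room to nucleate away from the spanning dark phase and
  time to grow; doubling disk mobility fits the slow protein-diffusion
  kinetics into the sweep budget.

Consequences of the scale-down, verified in the test suite and worth
keeping in mind when extrapolating:

* Contact events are far rarer than in long production runs; trend tests
  are statistical (Spearman, bootstrap) rather than point comparisons.
* Matched counts of r = 2–3 disks shift the composite system's critical
  point noticeably above τ = 1, displacing large-radius activity curves
  toward higher τ.
* With symmetric counts and a single common rate the well-mixed limit of
  f_A is 1/2, so activity spans roughly 0.1–0.5 rather than 0–0.9.
* Discrete-component effects (a handful of enzymes per dark domain) can
  qualitatively alter trends that are mean-field-like in large systems;
  the composition protocol documents one such case.

## Numerical choices

* Acceptance factors for the discrete ΔE values of integer couplings are
  table-lookups; non-integer couplings fall back to exp().
* Per-run randomness derives from numpy SeedSequence spawning: placement,
  spin assignment and dynamics consume independent child streams, and the
  per-(grid point, replicate) seeds of an experiment come from one master
  seed, so every table is exactly reproducible.
* The χ²/TV sampler validations enumerate their state spaces exactly
  (12870 fixed-m configurations; 240-state joint disk/defect space) and
  thin chain samples (every ~25 attempts) so test statistics are applied
  to effectively independent draws.
* Degenerate inputs: magnetizations unreachable on a finite lattice round
  to the nearest up-spin count; empty species lists are valid (bare
  membrane); zero targets make f_A undefined and raise.

## Known limitations

* No hydrodynamic interactions; lipid transport is purely diffusive.
* Inclusions are rigid uniform disks: no rotation, no patterned
  boundaries, no insertion/deletion, no direct disk–disk attraction.
* The displacement rule for lipids during disk moves is one valid
  symmetric, composition-conserving choice; other detailed-balance
  realizations exist and could shift diffusion constants (not
  equilibrium properties).
* At fixed composition the finite-lattice critical energy sits a few
  percent above the Onsager value (−√2); the package verifies
  finite-size convergence toward it rather than equality at L = 64.
* Pocketing at m = 0 requires the dark phase to be fragmented; on small
  scaled-down lattices just below τ = 1 the dark phase spans quickly and
  isolated pockets are rare, so pocketing statistics there are driven by
  the negative-m conditions.
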