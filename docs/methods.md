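# Methods

## Model

`polyplexmd` implements a coarse-grained bead–spring model of polyplex
self-assembly: flexible anionic chains (RNA; one bead = one nucleotide,
charge −e) and flexible cationic chains ("PEI"; one bead = two monomers at
50% protonation, charge +e) in implicit solvent, with one explicit
monovalent counterion (+e) per RNA bead and one co-ion (−e) per PEI bead.
All beads share the same mass m and diameter σ, and the thermal energy is
fixed at k_BT = ε.

Three interactions act between beads:

* **Excluded volume** — the repulsive part of the Lennard-Jones potential
  (WCA), truncated at 2^(1/6) σ.  By default the energy is shifted by +ε
  so it is continuous at the cutoff; the unshifted piecewise form is
  available (`wca_shifted=False`).  Forces are identical either way; the
  shifted form simply makes energy-conservation checks clean.
* **Connectivity** — harmonic springs U = ½ k (r − σ)² with
  k = 5000 ε σ⁻² between consecutive chain beads.  At k_BT = ε this keeps
  bond-length fluctuations within ~10 % of σ (measured max ≈ 7.4 % over
  10⁵ steps) and prevents chain crossing.
* **Electrostatics** — bare Coulomb U = k_BT l_b q_i q_j / r with Bjerrum
  length l_b = 1.168 σ.  With σ = 0.6 nm (the mean P–P distance of
  adjacent nucleotides) this maps to l_b ≈ 0.7 nm, water at room
  temperature, which anchors the reduced temperature to experimental
  conditions.  The relative dielectric constant is absorbed into l_b; no
  separate dielectric parameter is exposed.

Units: lengths in σ, energies in ε, masses in m, time in
τ = √(mσ²/ε), charges in e.  Helper functions expose the mapping used by
engines that work in physical units: 1/(4πϵ₀) = 138.935458 kJ mol⁻¹ nm e⁻²
and T = 120.27236 K for ε = 1 kJ/mol.

## Periodic electrostatics

Long-range electrostatics are evaluated by classical Ewald summation
(real-space erfc part over a Verlet pair list, reciprocal sum via
structure factors with a per-dimension phase-recursion table, self term).
The splitting is tuned from a single relative-accuracy parameter δ
(`coulomb_accuracy`): with p = √(−ln δ), α = p/r_c and
n_max = ⌈αLp/π⌉, which balances real- and k-space truncation errors at
~δ.  The default real-space cutoff is 10 σ; when the box is smaller than
20 σ the cutoff is reduced to just under half the box edge and the
splitting re-tuned (flagged in the run manifest).  Defaults: δ = 10⁻⁴ for
analysis-grade calls; sampling runs typically use δ = 10⁻³, comparable to
production practice for mesh Ewald engines.

Correctness anchors: the 8-ion rock-salt cell reproduces the NaCl
Madelung constant to <10⁻⁵ relative at δ = 10⁻⁶; energies are invariant
under the real/k-space split; a dipole-corrected direct lattice sum over
image boxes (`direct_lattice_sum`, tin-foil boundary) agrees on neutral
ion pairs; and forces match central-difference gradients of the energy to
≲10⁻⁶ relative.  The real-space erfc is evaluated by the
Abramowitz–Stegun 7.1.26 rational approximation (|error| < 1.5·10⁻⁷),
sharing one exponential with the force term.

A deliberate implementation note: neighbor handling uses Verlet pair
lists (cutoff + 0.4 σ skin, displacement-based rebuild), but the rebuild
is a brute-force O(N²) pass rather than a cell list.  At the scales this
package targets (N ≲ 5000, cutoffs ≥ box/4) cells cannot be smaller than
the cutoff, so they add bookkeeping without asymptotic gain; the rebuild
is amortized over ~20 steps.

## Building and equilibrating systems

`SystemSpec(n_rna, l_rna, n_pei, l_pei, box_edge, seed)` fixes a
composition; ion counts follow automatically (one per polymer bead), so
every system is exactly neutral.  Chains are inserted as self-avoiding
random walks with fixed bond length σ and a 0.9 σ overlap threshold
(bounded retries, `DensityError` on failure); this guarantees finite WCA
energies from the start.  Velocities are Maxwell–Boltzmann at T = ε/k_B,
zeroed total momentum, rescaled to the exact target.

Preparation follows a two-box protocol: the RNA+counterion and
PEI+co-ion subsystems are built, relaxed and equilibrated in separate
boxes of the full volume, then merged and re-equilibrated.  Relaxation of
each (possibly overlapping) configuration is: 100 MD steps with a
force-capped WCA ("soft core", cap 500 ε/σ, velocity clamp 10 σ/τ; the
functional form of the relaxation potential is our choice) → adaptive
steepest-descent minimization of the full potential (uphill moves are
reverted, so the energy never increases) → thermostatted equilibration.
The equilibration length is a parameter: full-scale protocol 2·10⁶ steps
(`FULL_SCALE_EQUILIBRATION_STEPS`), desk default 10⁵, test fixtures 10⁴–2·10⁴.

Aggregated starts (`build_aggregated_start`) take a converged isoelectric
(αN/P = 1) frame, insert additional PEI chains and matching co-ions at
random non-overlapping positions to reach the target charge ratio
(targets < 1 are rejected — the protocol is only defined for added
polycation), re-seed velocities, re-minimize and equilibrate.  The
aggregate's internal coordinates are preserved.

Seeding: one master seed per run; build, velocity, and thermostat streams
are derived through `numpy.random.SeedSequence` so runs are bitwise
reproducible.

## Dynamics

Leapfrog integration with dt = 0.005 τ and the stochastic
velocity-rescaling (Bussi) thermostat targeting T = ε/k_B.  The coupling
time is not prescribed by the physics; we use 0.5 τ (100 steps) — weak
enough not to distort diffusive dynamics (sensitivity: the kinetic
temperature stays within ±3 % for couplings 0.1–5 τ; transport changes
only through the usual global-rescale weak coupling).  The thermostat
rescales all velocities by a common factor, so zero total momentum is
preserved and no friction acts on collective motion; a Langevin
thermostat is deliberately avoided because uncorrelated random forces on
interior beads suppress the diffusion of large aggregates.  With the
thermostat disabled the integrator is plain symplectic leapfrog; measured
total-energy drift over 10⁴ steps is <1 % of the mean kinetic energy.

Trajectories carry wrapped and unwrapped coordinate channels; the
mean-square displacement uses multiple time origins (FFT algorithm) over
the unwrapped coordinates of a species selection.  A thermostatted ion
gas shows a late-lag log-log MSD slope of 1 within ±0.15, confirming
diffusive dynamics despite the absence of explicit solvent.

## Nanoparticle analysis

A nanoparticle (NP) is the transitive closure of polymer *chains* whose
minimum-image inter-bead distance is below 3.5 σ (single-linkage over
chains via connected components; an isolated chain is a single-chain NP).
Ions within 3.5 σ of any member bead are attached to the NP of their
nearest polymer bead.  Clusters are reconstructed across periodic
boundaries by breadth-first minimum-image placement from an arbitrary
seed bead over the bond+proximity adjacency — required for gyration
metrics and unstated in typical method descriptions.

Conventions are deliberately mixed, following the observable definitions:

* **Gyration metrics** (eigenvalues λ₁² ≥ λ₂² ≥ λ₃², R_g = √Σλᵢ²,
  relative shape anisotropy κ² = 3/2 Σλᵢ⁴/(Σλᵢ²)² − 1/2) use polymer
  beads only.  κ² is exactly 1 for collinear beads and exactly 0 for a
  degenerate tensor (e.g. cube vertices).  The eigenvalue route agrees
  with the direct mean-square-distance form of R_g to machine precision.
  Single-bead NPs report R_g = 0 and κ² = NaN.
* **Hydrodynamic radius** (Kirkwood double sum,
  1/R_h = ⟨1/r_ij⟩ over ordered distinct pairs) and the **NP charge**
  include the attached ions.  Closed forms: two beads at distance d give
  R_h = d; an equilateral triangle of side d gives R_h = d.
* **ζ potential**: assuming spherical symmetry (good near and above the
  isoelectric point), ζ = l_b ∫ Q(r)/r² dr from the shear surface (R_h)
  to 50 σ, where Q(r) is the cumulative charge of *all* beads — polymers
  and ions, attached or free — within minimum-image distance r of the
  NP's polymer-bead centre of mass.  Q(r) is a step function over the
  exact sorted distances and the integral is evaluated in closed form
  segment by segment (no histogram, no quadrature error).  The 50 σ
  upper limit presumes a box of ≥100 σ; smaller boxes should pass a
  smaller `r_max`.  Whether free (unattached) ions belong in Q(r) is a
  genuine ambiguity; we include them, since the defining quantity is "the
  charge inside a sphere around the NP centre".

**Manning condensation check**: in a PEI-free solution the fraction of
RNA charges neutralized by condensed counterions is compared to
φ = 1 − σ/l_b ≈ 0.144.  Two observables are provided.
`manning_fraction` is the fraction of RNA *beads* with ≥1 counterion
within a binding cutoff (default 3.5 σ, consistent with the NP ion
shell) — useful as a coverage measure, but at 3.5 σ it counts the
diffuse double layer and saturates near 1 in any feasible geometry.
`condensed_counterion_fraction` is the neutralized-charge fraction that
Manning's formula actually predicts: condensed counterions (within the
conventional strongly-bound 2 σ shell of the chain) per RNA charge.  At
this model's weak Coulomb coupling (ξ = l_b/σ = 1.168, barely above the
condensation threshold) there is no sharp condensed/diffuse boundary, so
the value is criterion-sensitive — measured at the reference density:
≈ 0.04 within l_b, ≈ 0.17 within 2 σ, ≈ 0.27 within 3.5 σ, against the
prediction 0.144.  The condensation test uses the 2 σ neutralized-charge
form; the sensitivity above is the honest context for that agreement.

## Ensemble statistics

The order parameter n_NPs* is the number of RNA-containing NPs divided by
N_RNA: free PEI clusters are excluded (the observable counts NPs against
RNA chains and saturates at 1 in polycation excess; at αN/P = 0 each bare
RNA chain counts as one NP).  The free-energy projection
F = −k_BT ln P̂(n_NPs*) uses one bin per attainable cluster count
(width 1/N_RNA); empty bins carry no value; profiles are shifted to
min F = 0.  A parabola is fitted over bins with F ≤ F_min + 2 k_BT (our
choice: weights the well around the minimum); with fewer than three such
bins the minimum falls back to the modal bin.  Against an exact Gaussian
oracle (10⁵ draws), the fitted minimum is recovered within bin resolution
and the curvature within 10 %.

Scaling collapse: αN/P* = (αN/P − 1)·c_RNA/c_ref + 1 and
N/P* = (N/P − N/P_iso)·c_RNA/c_ref + N/P_iso (N/P_iso = 1/α in the
model).  The collapse identity — equal (αN/P − 1)·c_RNA implies equal
αN/P* — is exact algebra and is property-tested.  The reference
concentration c_ref,RNA is a required parameter of the transform; no
default is baked in.

Condition summaries average the second half of each replicate's frames
(the equilibrated window; the discard rule is our choice), then take mean
and standard deviation across replicates.  Per-NP averaging within a
frame is unweighted by default; RNA-mass weighting
(`weight="rna_chains"`) is offered and the choice is recorded in the
table metadata.  Single-replicate conditions report std = 0 with a flag.

## Scale presets and the problem sizes used by the test suite

The full-scale preset (`full_scale_config`) encodes the reference grid: 8×100
RNA beads in a (200 σ)³ box (0.7 mM nucleotides), l_PEI = 10, N_PEI up to
3000 (αN/P up to 37.5), 2·10⁸ production steps, 4 replicates.  The desk
preset (`desk_config`) keeps the same RNA bead density with 2×30 RNA and
≥10⁶ production steps.

The test suite uses smaller, more concentrated fixtures chosen so that
chain encounter times fit a desk run:

* isoelectric aggregation and start-state consistency: 2 RNA × 30,
  6 PEI × 10, box 18 σ, 10⁴ equilibration + 8·10⁴ production steps;
* polycation-excess dissolution: 2 RNA × 10, 32 PEI × 10 (αN/P = 16),
  box 36 σ, 10⁴ + 5·10⁴ steps.  The box must stay dilute enough that
  free PEI chains do not percolate the 3.5 σ linkage graph — in a
  (15 σ)³ box the cluster *definition* (not the physics) degenerates;
* Manning condensation: 1 RNA × 100 with its 100 counterions, box
  100 σ (the reference ~0.8 mM counterion density), real-space cutoff
  30 σ, 3·10⁴ + 6·10⁴ steps;
* single-chain condensation (R_h at αN/P = 1 below αN/P = 0): 1 RNA × 30
  with and without 3 PEI × 10, box 24 σ, 10⁴ + 3·10⁴ steps.

At these concentrations the phase behaviour being probed is
concentration-robust: below the isoelectric point the state depends only
on the charge ratio, and higher polycation excess only strengthens
dissolution.  What the desk fixtures do *not* probe is the quantitative
location of the aggregation–dissolution midpoint, finite-size scaling of
the peak size at αN/P = 1, or the dilute-regime Debye screening — those
require the full-scale preset.

## Known limitations

* The synthetic systems are strong polyelectrolytes with fixed charges —
  no titration, pH response, chain stiffness, hydrophobicity, or
  sequence effects; agreement of tests says nothing about those.
* No explicit solvent or hydrodynamic interactions: diffusion arises
  from ion collisions, so absolute time scales are not mapped to
  experiments.
* The ζ integration assumes spherical symmetry; for stretched,
  strongly anisotropic complexes (αN/P ≪ 1) it is a rough descriptor.
* Short desk-scale chains (l_RNA ≤ 30) under-resolve Manning
  condensation end effects; the condensation test uses l_RNA = 60 as a
  compromise between end effects and run time.
* The direct lattice-sum oracle converges slowly (cube shells with a
  dipole correction) and is only intended for few-bead fixtures.
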