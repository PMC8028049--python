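# Methods

This note documents the models implemented in `reaxkit`, the numerical
choices behind them, and what the synthetic fixtures do and do not
demonstrate.

## Potential energy model

The total energy is the standard bond-order reactive force-field sum

    E = E_bond + E_lp + E_over + E_under + E_val + E_pen + E_coa
      + E_tors + E_conj + E_hbond + E_vdW + E_Coul + E_charge

with every contribution in kcal/mol, distances in Angstrom, and charges in
electrons.  The functional forms follow the mainstream 2008-era ReaxFF
dialect (the one consumed by the major open-source reactive-MD codes), since
parameter files in the standard fixed `ffield` format are written against
that dialect:

- **Uncorrected bond orders** are the three-exponential distance law with
  separate sigma, pi and double-pi channels; a channel is inactive when
  either element's corresponding radius is non-positive.  The sigma channel
  is scaled by `(1 + bo_cut)` and shifted down by the global bond-order
  cutoff `bo_cut` (general parameter 30, stored as 100x), so the total
  uncorrected bond order reaches zero *continuously* at the cutoff distance
  instead of being truncated with a jump.  Pairs whose raw total falls below
  `bo_cut` are dropped from the bonded graph.
- **Overcoordination corrections** multiply the raw bond orders by the
  standard `f1(Delta'_i, Delta'_j)` and `f4 f5` (1-3 correction) factors,
  gated per bond record by its `ovcorr` and `v13corr` flags.  Pi channels
  carry `f1^2 f4 f5`.
- **Lone pairs** use the truncation-toward-zero integer convention of the
  C implementations when splitting the electron excess `Delta_e` into lone
  pairs; the lone-pair energy is `p_lp2 * Delta_lp / (1 + exp(-75 Delta_lp))`.
- **Over/undercoordination energies** use the lone-pair-corrected
  `Delta_lpcorr` with the pi-resonance sums over neighbours.
- **Valence angles** use the `f7 f8` bond-order/coordination factors and the
  SBO -> theta_0 equilibrium-angle interpolation with `p_val8`-weighted
  lone-pair adjustment; the three-body penalty and conjugation (coalition)
  terms follow the standard forms.  Angles and torsions are enumerated only
  over bonds whose corrected bond order exceeds the three-body threshold
  (0.001), and the `BO - 0.001` offset is used inside `f7`, `f10`, and `f12`
  so those terms switch on from exactly zero.
- **Torsions** use `f10`, the `f11` overcoordination factor of the central
  bond, the `2 - BO_pi - f11` exponent on the `V2` barrier, and the
  sin(theta) gating of both flanking angles; the four-body conjugation term
  uses `f12`.  Near-collinear flanking angles (|n| < 1e-7) are skipped: the
  energy they would contribute vanishes with sin(theta) while the dihedral
  gradient formula becomes singular.
- **Hydrogen bonds** are donor-H...acceptor triples where the donor-H
  corrected bond order exceeds 0.01 (configurable), the acceptor lies within
  7.5 A of the hydrogen, and both elements carry the appropriate donor (1) /
  acceptor (2) role flags.  The angular factor is `sin^4(theta/2)` at the
  hydrogen vertex with the `exp(-p_hb3 (r0/r + r/r0 - 2))` radial envelope.
- **Van der Waals** is the shielded Morse form with the `f13` distance
  shielding and pair parameters combined geometrically (`r_vdW` pair =
  2 sqrt(r_i r_j)); off-diagonal records override pair values.  No inner
  wall and no low-gradient dispersion variant are implemented.
- **Coulomb** is the shielded kernel `q_i q_j / (r^3 + (gamma_i
  gamma_j)^{-3/2})^{1/3}` tapered to the cutoff, evaluated for *all* pairs
  within the taper radius, bonded or not.
- **Taper**: all nonbonded terms are multiplied by the 7th-order polynomial
  switching function whose value and first three derivatives vanish at the
  cutoff (the taper radius, general parameter 13; 10 A in the bundled
  parameter set).  It is evaluated in the cancellation-free factored form
  `(1-u)^4 (1 + 4u + 10u^2 + 20u^3)`, which is exactly equal to the
  conventional monomial form but numerically stable near the cutoff.

### Charges (EEM)

Partial charges minimize `sum_i (chi_i q_i + eta_i q_i^2) + E_Coul(q)`
subject to `sum q_i = Q`, solved as the (N+1)-dimensional KKT linear system.
Electronegativity and hardness are tabulated in eV and converted with
1 eV = 23.060549 kcal/mol.  Charges are re-equilibrated at every energy
evaluation; there is no frozen-charge shortcut.

### Forces

Analytic forces are assembled by manual reverse-mode differentiation:
each term deposits adjoints on corrected bond orders, per-atom coordination
sums, and geometric coordinates; these are propagated through the
bond-order correction back to distances.  The derivative of the charges with
respect to coordinates is *not* computed.  Because the EEM charges minimize
the electrostatic energy under the charge constraint, the chain-rule term
through `dq/dx` vanishes at the solution (Hellmann-Feynman); the residual is
set by linear-solver precision and is bounded in the test-suite at
< 1e-6 kcal/mol/A.  The test-suite and the acceptance script verify every
term against central differences (step 1e-5 A) to < 1e-4 kcal/mol/A.

### Periodic boundaries

Only orthorhombic cells are supported.  Because the production box
(13.0 x 16.4 x 15.24 A) is smaller than twice the 10 A taper radius, the
neighbour list enumerates *all* lattice translations inside the cutoff
sphere -- including an atom's interactions with its own periodic images --
rather than using the minimum-image convention.  Self-image pairs contribute
to the EEM matrix diagonal.  No Ewald summation is used; electrostatics are
tapered, consistent with the shielded-Coulomb convention of this family of
force fields.

## Geometry optimization and dynamics

Optimization is L-BFGS with analytic gradients, converged on the
root-mean-square gradient (RMSG) over all 3N Cartesian components.
Production-style relaxations use 1e-3 kcal/mol/A before dynamics and 1e-4
for equilibrium-geometry comparisons.  On non-convergence the best-so-far
structure is attached to the raised error.

Dynamics is velocity Verlet with the Berendsen weak-coupling rescale
`lambda = sqrt(1 + (dt/tau)(T0/T - 1))` applied after each step; `tau = dt`
pins the kinetic temperature exactly, `tau = None` gives NVE.  Production
parameters are dt = 0.1 fs and tau = 25 fs.  Initial velocities are
Maxwell-Boltzmann at the target temperature with centre-of-mass motion
removed, seeded for exact reproducibility.  Instantaneous temperature uses
3N - 3 degrees of freedom for isolated systems and 3N for periodic ones.
NVE conservation on the water dimer (dt = 0.05 fs, 10^4 steps) holds to
< 1e-2 kcal/mol, and the drift scales as expected for an order-2 integrator
when the step is halved.

## Training

Training data are built by scanning one internal coordinate at a time --
bonds (0.2-0.4 A increments), valence angles and torsions (10 degree
increments), and rigid cluster-water separations -- displacing a rigid
moving fragment so that every other internal coordinate is untouched.  The
default moving fragment is the connected component on the far side of the
scanned coordinate (the smaller side for bonds); cyclic coordinates require
an explicit set.

The cost is the weighted sum of squared residuals over training-partition
entries; energy entries are force-field energy differences
(distorted - equilibrium), charge entries are EEM charges.  The weight
multiplies the squared residual.  Validation-partition entries are excluded
from the cost and used only in reports.  A failed evaluation contributes a
penalty ceiling of 1e10 instead of raising, so a swarm iteration survives
pathological parameter vectors.

The optimizer is gbest particle-swarm with c1 = c2 = 2.0, inertia decaying
linearly 0.9 -> 0.4 over the run, per-dimension velocity clamped to half the
bound range, positions clamped to bounds, Gaussian-mutation respawn of the
worst 20% of agents around the global best (sigma = 0.1 x bound range per
dimension; the best agent is never respawned), and periodic bounded
Nelder-Mead relaxation of every agent (default every 20 iterations --
relaxing at every iteration would dominate the run time).  Training can be
staged: a charges-only stage fits charge-related parameters to reference
charges first, then a full stage fits everything else, mirroring the
iterative protocol.  The plain quadratic cost is used throughout; no
transformed-cost variant is implemented.

## Analysis

- `aligned_rmsd` minimizes RMSD over translation, proper rotation,
  per-element permutation, and overall inversion by alternating Hungarian
  assignment on squared distances with Kabsch alignment, from several random
  initial orientations and both parities.  It matches an exhaustive
  permutation x parity oracle on 6-atom systems to 1e-8 A.
- Hydrogen bonds use donor-acceptor cutoffs of 3.7 A and 20 degrees, the 20
  degrees being the deviation from linearity measured between the D->H and
  D->A directions (a configurable alternative applies 160 degrees at the
  hydrogen vertex).  Covalent D-H assignment uses a covalent-radius distance
  heuristic.  With a cluster selection, only bonds with exactly one partner
  in the cluster are counted.
- Trajectory statistics average per-frame observables over a time window
  (production protocol: the last 10 ps of 16 ps); the Fe-S distance pools
  the four symmetry-equivalent Fe-S pairs within each frame before the time
  average; the ring dihedral is folded to [0, 180] degrees; SDs are
  population SDs over frames.
- Deviation reports count each internal coordinate once per orbit of the
  element-preserving automorphism group of the bonded topology graph, so
  symmetry-equivalent bonds/angles/torsions are not double-counted.
- Iron coordination states are classified by counting oxygens within 2.8 A
  of each iron (3/4/5 = trigonal/tetrahedral/trigonal-bipyramidal);
  the cutoff is configurable.

## Synthetic fixtures

The bundled H/O/Fe/S parameter set is a self-contained toy force field
assembled for testing and demonstration.  Water is a stable bent molecule
(O-H 0.94 A, H-O-H 96 degrees after relaxation), the water dimer forms a
single hydrogen bond, Fe2S2 relaxes to a planar rhombus, and water oxygens
bind iron sites.  It was *not* fitted to quantum-chemical reference data, so
passing tests demonstrate internal correctness of the machinery (energies,
gradients, integrators, optimizers, counters) -- not quantitative accuracy
against any electronic-structure method.  Quantitative work requires a
force field trained on real reference data in the same `ffield` format.

The solvated-box generator packs rigid waters (0.9572 A / 104.52 degrees)
on a jittered lattice with seeded random orientations around a centred
solute, rejecting heavy-atom contacts below 2.0 A under minimum image.  The
production-style box is one Fe2S2 cluster plus 78 waters in a
13.0 x 16.4 x 15.24 A cell (238 atoms).  Synthetic training sets evaluate a
known generating force field on scan structures (optionally with seeded
Gaussian noise), which yields exactly-zero cost at the generating
parameters and enables parameter-recovery testing.

## Problem sizes

The default test-suite and the acceptance script use gas-phase fixtures of
3-16 atoms, 20-water boxes for counting oracles, a two-parameter swarm
recovery with 20 agents, NVE runs of 10^4-2x10^4 steps on the water dimer,
and a 238-atom solvated-cluster NVT run (L-BFGS pre-relaxation, a 50 fs
strongly-coupled equilibration stage with tau = 1 fs, then 100 fs of
production at tau = 25 fs with statistics over the second half).  These
sizes exercise every code path, including the small-box periodic-image
machinery, while a full 16 ps production run of the 238-atom box is
available through the same API and CLI for users who want the complete
solvation protocol.  A freshly packed box keeps relaxing on this time scale,
so the scaled-down run reports a window temperature somewhat above the
300 K target, and cluster-water hydrogen bonds -- which require
picosecond-scale water reorientation -- remain sparse; the total
(water-water) hydrogen-bond count is already well sampled.

## Known limitations

- Orthorhombic cells only; no Ewald electrostatics; no cell lists (pair
  enumeration is O(N^2) per image shift, adequate below ~10^3 atoms).
- No ACKS2 or QTPyE charge models; no inner-wall or lg-dispersion van der
  Waals variants; no triple-bond (C2-style) corrections.
- The analytic-force path covers every implemented term; torsions whose
  flanking angles are numerically collinear are skipped as described.
- Geometry training entries relax structures with a loose RMSG (1e-2) for
  cost evaluation, which is a compromise between fidelity and cost.
- Berendsen is the only thermostat; it does not sample a canonical ensemble
  strictly, matching the simulation protocol it reproduces.
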