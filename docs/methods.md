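# Methods

`remdsearch` implements a conformational-search workflow for small
molecules: a molecular-mechanics energy model, Langevin dynamics, replica
exchange over a temperature ladder, and quality-threshold (QT) cluster
analysis of the lowest-temperature trajectory.  This note records the
models, the numerical choices, and what the packaged synthetic systems do
and do not demonstrate.

## Energy model

The potential is the standard additive form

    V(r) = Σ_bonds k_b (r − r_eq)²
         + Σ_angles k_θ (θ − θ_eq)²
         + Σ_dihedrals (ϑ_n/2)[1 + cos(nφ − γ)]
         + Σ_{i<j} 4 ε_ij [(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶]
         + Σ_{i<j} C q_i q_j / r_ij

in AKMA units (kcal·mol⁻¹, Å, amu, elementary charges, fs;
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹, C = 332.0636 kcal·mol⁻¹·Å·e⁻²).
Lorentz–Berthelot combination builds the pair LJ parameters; 1-2 and 1-3
pairs are excluded and 1-4 pairs scaled (defaults 0.5 for LJ and 1/1.2 for
Coulomb, the convention of the force-field family these parameters
emulate; both factors live in the parameter file).

**Cutoffs.**  LJ interactions are multiplied by a C¹ cubic switching
function in r², active between `r_switch` = 9 Å and `r_cut` = 10 Å
(evaluated in smoothstep form, which is branch-free and exactly continuous
in energy and force at both radii).  Electrostatics use shifted-force
truncation at `r_cut`: `E = Cq_iq_j(1/r − 2/r_c + r/r_c²)`, whose energy
*and* force vanish continuously at the cutoff.  This deliberately replaces
Ewald summation: the systems this package targets are a few thousand atoms
at most, and the sampling and clustering machinery under study is
independent of the long-range electrostatics treatment.  Periodic systems
use the minimum-image convention in an orthorhombic cell, applied to
bonded terms as well so the energy is exactly invariant under translating
any atom by a lattice vector; the cell must exceed twice the cutoff.

**Implicit solvent.**  The generalized-Born term is the classic pairwise
Still expression `E = −(C/2) Σ_ij (1 − e^{−κ f_ij}/ε) q_i q_j / f_ij` with
`f_ij = sqrt(r² + a_i a_j exp(−r²/4a_ia_j))`, intrinsic Born radii `a_i`
taken from the parameter file, solvent dielectric ε = 78.5 and
Debye–Hückel screening from a 0.2 M 1:1 ionic strength by default.  The
self terms (i = j, f = a_i) give the Born solvation energy of each charge.
ε = 1 means no dielectric contrast and returns exactly zero.  More
elaborate GB variants (effective-radius recomputation, surface-area
terms) are out of scope.

**Restraint.**  An optional solute centre-of-mass restraint
`E = ½ k |COM − target|²` (default k = 5.0 kcal·mol⁻¹·Å⁻², target = box
centre) keeps the solute centred during explicit-solvent equilibration;
its force is distributed mass-weighted over the solute atoms.

**Gradients.**  Every term has an analytic gradient; the test suite
audits each against central finite differences (relative error < 1e-5) on
randomized geometries.  A fused numba kernel evaluates all terms in one
pass when numba is importable; the pure-numpy implementations are the
reference, and the suite asserts the two routes agree to ~1e-13.

## Dynamics

The integrator is the BAOAB splitting of Langevin dynamics (kick –
drift – Ornstein–Uhlenbeck refresh – drift – kick), chosen for its
configurational-sampling accuracy at the 1 fs default timestep.  With
zero friction the O step is the identity and the scheme is exactly
velocity Verlet — time-reversible and energy-conserving, which the tests
exploit.  Default friction is 1 ps⁻¹.

Bonds containing hydrogen are constrained by SHAKE: position corrections
along the pre-step bond directions, iterated to a relative tolerance of
1e-8 (configurable within (0, 1e-3]), with an error raised after 500
iterations.  Constraints are applied after each drift half-step, the
position correction is propagated into the velocities, and relative
velocities along constrained bonds are projected out after each kick and
refresh.  Water is flexible-bonded (two constrained O–H bonds plus a
harmonic bend) rather than rigid three-site; this is a declared
approximation of the usual rigid model and is consistent throughout.

Degrees of freedom for temperature reporting are 3N − N_constraints − 3
(centre-of-mass momentum is removed at velocity initialization).
Velocities are initialized from the Maxwell distribution at the target
temperature with constrained components projected out.

All propagation accepts a leading batch dimension: an m-replica ensemble
advances as one vectorized pass per step with per-replica target
temperatures and per-replica RNG streams (spawned from one seed via
`SeedSequence`), so results are independent of any execution backend and
bitwise reproducible.  This replaces process-level parallelism; the CLI
accepts the conventional worker-count flag for interface compatibility,
and results are trivially worker-independent.

## Replica exchange

Temperatures follow a geometric ladder `T_i = T_min (T_max/T_min)^((i−1)/(m−1))`
(default 24 replicas, 298–500 K), which keeps the potential-energy overlap
of neighbours roughly constant.  Every cycle (default 1000 steps) one
exchange phase runs: even neighbour pairs on even cycles, odd pairs on odd
cycles.  A swap between slots i and j is accepted with probability

    P = min[1, exp((1/k_B)(1/T_i − 1/T_j)(V_i − V_j))]

drawing u ~ U(0,1) and accepting iff u < P.  On acceptance, coordinates
are swapped and the swapped velocities are rescaled by √(T_dest/T_src) so
each replica keeps a Maxwell distribution at its own temperature.  The
state is stored per temperature slot; a walker-identity trace provides
the mixing diagnostic.  Acceptance statistics are recorded per neighbour
pair and as the ensemble average.

## Cluster analysis

The lowest-temperature trajectory is analysed under the pairwise RMSD
metric `d_ij = [(1/N) Σ_k |r_k^(i) − r_k^(j)|²]^{1/2}` evaluated after
optimal superposition (Kabsch, proper rotations only).  By default every
pair is superposed independently (a batched SVD over pair blocks); a
faster approximate mode aligns all frames to frame 0 first.  The RMSD
mask defaults to all solute atoms, with a heavy-atom-only option.

QT clustering tries every remaining frame as a candidate centroid,
collects the remaining frames within the cutoff (default 1.0 Å), keeps
the largest candidate cluster (ties: lowest frame index, which makes the
result invariant to frame order), removes its members, and repeats until
the requested number of clusters (default 5) or exhaustion.  Unassigned
frames are reported as an explicit remainder.  Cluster populations
p_i = n_i/n_total yield relative Gibbs energies
ΔG_i = −k_B T ln(p_i/p_1).

For one-dimensional torsional models the exact basin populations
`p_i = ∫_i e^{−V/k_BT} dφ / ∮ e^{−V/k_BT} dφ` are computed by adaptive
quadrature (~1e-10 relative) and serve as the independent oracle for the
end-to-end sampling checks.

## Synthetic systems

The fixture factory supplies fully parametrized systems; no automatic
typing or charge derivation exists in this package (3D structures plus a
native parameter file are the only input route).

- `harmonic3d` — an anchor plus ten satellites on isotropic springs
  (k = 10 kcal·mol⁻¹·Å⁻², r_eq = 0): thirty quadratic degrees of freedom
  with known statistics, the thermostat benchmark.  Several independent
  quadratic dofs keep the sampling error of ⟨PE⟩ a few times smaller than
  the 2% band used in the thermostat check.
- `double_well_torsion` — a four-bead chain whose single torsion sees
  V(φ) = (0.8/2)(1+cos φ) + (2.5/2)(1+cos(2φ−π)): trans (φ = π) at 0,
  cis at +0.8 kcal·mol⁻¹, barrier 2.9 from trans.  Nonbonded terms and
  1-4 couplings are zero, so the torsion marginal is exactly
  ∝ e^{−V(φ)/k_BT} (the bond/angle Jacobian factorizes), making REMD +
  clustering quantitatively checkable against quadrature.  The terminal
  beads sit on 3.7 Å bonds (centre-of-mass stand-ins for bulky end
  groups) so the two conformers are ~2.3 Å apart in minimized RMSD and
  the barrier-top geometry is more than 1 Å from either well — distinct
  conformers must be separated by about twice the cluster cutoff for
  centroid-based QT clustering to resolve them, exactly as for real
  molecules.
- `butane_like` — united-atom four-bead chain, one rotatable bond, anti
  global minimum; the rotor-key enumeration example.
- `minidrug` — a ~50-atom branched neutral molecule (quaternary core,
  butyl chain, hydroxyl and aminoethyl arms, methyl decorations) with
  three rotatable bonds, generic alkane/alcohol/amine-like parameters and
  internally neutral polar-group charges.  Built from a deterministic
  heavy-atom tree, hydrogens completed tetrahedrally, then relaxed by
  L-BFGS (deterministic).  The stand-in for an automatically parametrized
  drug.
- `water_box`, `solvated_minidrug` — three-site flexible water
  (O–H 0.9572 Å, 104.52°, q_O = −0.834) placed on a jittered cubic
  lattice at 0.0334 molecules·Å⁻³ with per-axis counts rounded so the
  mean density matches the target; waters whose oxygen lies within 2.4 Å
  of the solute are removed.  Solvation pads the solute bounding box by
  10 Å per side.  Charged cells are neutralized by swapping the waters
  farthest from the solute for Na⁺/Cl⁻ (deterministic farthest-first
  placement).

What the fixtures do not emulate: real torsional coupling to nonbonded
terms in the double-well benchmark (deliberately, to keep the oracle
exact), conformational frustration of real drugs, pre-equilibrated water
structure (the lattice relaxes during equilibration), rigid water, and
polarization.  Passing tests therefore demonstrate the correctness of the
sampling and analysis machinery, not force-field accuracy for any real
compound.

## Conformer enumeration

Rotor keys enumerate every combination of discrete settings (default
120° grid) around the listed rotatable bonds; setting g rotates the
smaller side of the bond (ties rotate the side holding the higher atom
indices) by g·360°/resolution from the input geometry.  Combinations
above a configurable cap (default 20000) are refused explicitly.
Structures are ranked by gas-phase energy, ties broken by key, and the
lowest-energy structure is the selected starting conformer.  Ring bonds
are rejected as non-drivable.

## Workflow scales

Time-based protocol lengths are expressed as step counts.  Desk-scale
defaults (minutes on one core) are 2000 equilibration steps and 50
cycles × 1000 steps of sampling; `workflow.FULL_SCALE_PRESET` records the
production-scale protocol (10⁶ equilibration steps, 10⁴ cycles — 1 ns +
10 ns per replica at 1 fs).  The acceptance script runs 202 cycles
(101 exchange attempts per neighbour pair) on the ~50-atom fixture; the
statistical checks in the test suite use 10⁶-step thermostat runs and a
16 000-cycle double-well REMD run, sized so their Monte-Carlo standard
errors sit a factor ≳2 below the tolerances they are tested against.

## Known limitations

No neighbour lists (dense pair enumeration bounds practical system size
to a few thousand atoms); no barostat (explicit-solvent boxes are built
at approximately liquid density and sampled at constant volume); no Ewald
electrostatics; no rigid-body water; torsion-driving enumeration ignores
stereochemistry; the QT candidate search is O(n²) in trajectory frames
(thin the trajectory before clustering very long runs).
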