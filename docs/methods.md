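# Methods

`bilff` models triazolium/benzoate ionic liquids — solvents of practical
interest because they dissolve cellulose near room temperature — with an
all-atom fixed-charge force field, a compact MD engine, and the
structural/dynamical analyses used to characterize hydrogen bonding in
these systems.  This note records the model, its assumptions, the
numerical choices, and what the bundled synthetic data can and cannot
demonstrate.

## Potential-energy model

The potential is the OPLS-AA functional form:

U = Σ_bonds k_l (l − l₀)² + Σ_angles k_θ (θ − θ₀)²
  + Σ_dihedrals Σ_{n=1..4} (V_n/2)[1 ± cos(nφ)]
  + Σ_{i<j} f_ij { 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶] + q_i q_j e²/(4πε₀ r_ij) }

Bond and angle terms carry **no ½ prefactor** (the published constants
are defined that way).  Cross Lennard-Jones parameters use **geometric
means for both σ and ε**.  The published atom types, charges, LJ
parameters and all bonded constants for the
1-ethyl-3-methyl-1,2,3-triazolium cation ([EMTr]⁺) and the benzoate
anion ([OBz]⁻) are embedded in `bilff.parameters` verbatim.

Key modelling assumptions:

- **Scaled ionic charges.** Each ion carries a net charge of ±0.82 e,
  a widely used mean-field surrogate for electronic polarization in
  ionic liquids.  The embedded per-atom charges close at exactly
  ±0.820 e per ion (asserted in the test suite).
- **Type aliases.** The nomenclature table lists the N-methyl carbon
  (CM) and two hydrogen families (HM on the N-methyl, HE on the
  ethyl-terminal CH₃) without their own charge rows.  CM carries the C1
  parameters, HM the H1 parameters and HE the HC parameters; this is
  the unique assignment under which the cation's charge sum closes at
  +0.82 e exactly.  (H1 is the type of hydrogens on carbons bonded to
  ring nitrogen; HC is the aliphatic-terminal type.)
- **Exclusions.** Intramolecular 1-2 and 1-3 non-bonded interactions
  are removed; 1-4 interactions are scaled by f₁₄ = 0.5 for both LJ and
  Coulomb — the OPLS-AA convention, which the force field's functional
  form is based on.  The published source does not state f₁₄
  explicitly; the factor is configurable in `ExclusionPolicy`.
- **Water** is rigid four-site TIP4P-Ew: three SHAKE constraints
  (two O–H at 0.9572 Å, H–H closing the 104.52° angle) and a massless
  M site on the bisector at 0.125 Å from O carrying the negative
  charge.  Because the parents are rigid, the M site is an exact linear
  combination of O, H1, H2 (coefficient 0.10667), and forces on it are
  redistributed with the same weights.  The TIP4P-Ew constants are the
  standard literature values and ship as a bundled parameter file
  (`data/tip4pew.bff`) rather than embedded code constants, since they
  belong to a different model family.
- **Partially supported species.** The imidazolium cation ([EMIm]⁺)
  and acetate ([OAc]⁻) graphs are included for composition/density
  bookkeeping (their molar masses need only elements), but their full
  parameter sets belong to the earlier generation of this force-field
  family and are *not* embedded; only the values needed for the
  documented parameter-delta checks are (ring-proton q = 0.150,
  σ = 1.62 Å; carboxylate O q = −0.66 e).  Simulating these species
  requires merging a user parameter file in the documented `.bff`
  format; conflicting redefinitions of embedded values raise an error.

## Electrostatics

Two solvers share one exclusion policy:

- **Minimum-image direct sum** (optionally truncated): exact for
  isolated clusters in large boxes; used by most tests.
- **Classic Ewald summation** with tinfoil boundary conditions:
  real-space erfc sum over minimum-image pairs within r_c, reciprocal
  sum over a half-space of k vectors (conjugate symmetry), self term,
  and a neutralizing-background term for charged systems.  The
  splitting parameter is α = s/r_c with s = √(−ln a) for requested
  accuracy a, and the reciprocal cutoff follows from the same balance.
  Excluded and scaled intramolecular pairs are corrected by
  subtracting (1 − f_ij)·erf(α r)/r at the nearest image, while the
  real-space sum uses the *scaled* charge product — together this
  leaves exactly f_ij q_i q_j/r for bonded neighbours.  The
  implementation is validated against the closed-form Madelung
  energies of the rock-salt and CsCl lattices (1.747564…, 1.762674…),
  an Evjen-weighted direct sum, an independence-of-split check, and
  central-difference force/virial oracles.  Ewald replaces the
  particle-mesh solver a production engine would use: identical
  physics, simpler to verify at this scale.
- **Lennard-Jones** is truncated at 8 Å by default (the published
  cutoff, 800 pm) with no tail correction; a mean-field tail correction
  for energy and virial is available (`tail=True`) and is used in the
  reduced NpT density runs, where the box only admits a ~7 Å cutoff.

Internal units are Å, fs, amu, e, kJ/mol; pm appears only at I/O
boundaries.  The Coulomb constant is e²/(4πε₀) =
1389.35457644382 kJ mol⁻¹ Å e⁻².

## Dynamics

Velocity-Verlet integration at a default 0.5 fs timestep with:

- **Berendsen** weak-coupling rescaling (default coupling 1 fs, used
  only in the 500 K scramble stage, as printed in the protocol);
- **Langevin** (exact Ornstein–Uhlenbeck velocity update, seeded,
  center-of-mass motion re-zeroed every step — documented behaviour);
- **Nosé–Hoover chains** of length 2 (coupling 100 fs default; the
  chain length is this package's choice, the source states only the
  coupling constant);
- an isotropic **Nosé–Hoover (MTK-style) barostat** (coupling 2000 fs
  default, target 1 atm — the target pressure is never stated in the
  source and 1 atm is assumed) with its own thermostat link on the
  cell momentum.  The barostat works in the *molecular* formulation:
  the pressure it couples to is the molecular (COM) pressure
  P = (2K_trans + W − Σ_i F_i·(r_i − R_com))/3V — the lever-arm
  correction removes all intramolecular contributions, so rigid-water
  constraint forces never enter — and cell scaling moves molecular
  centers, keeping rigid molecules rigid.  The atomic virial Σ r·F is
  validated against a numerical volume derivative; the molecular
  pressure reproduces ~1 atm (within the few-kbar instantaneous noise
  of a 64-molecule box) for rigid four-site water at its ambient
  density, where the raw atomic-virial estimate is off by >10⁴ atm.
- **SHAKE** (vectorized Jacobi iterations along pre-step reference
  vectors, relative squared-distance tolerance 10⁻⁶) plus a RATTLE
  velocity projection keeps water rigid.

Validated properties: NVE drift < 10⁻⁴ relative over 10⁴ steps,
Nosé–Hoover ⟨T⟩ within 2 % and Langevin within 5 % on a 100-particle LJ
fluid, ideal-gas NpT volume within 10 % of NkT/P, bitwise seed
determinism.

The four-stage protocol (`run_protocol`) mirrors the published
workflow: seeded random-insertion packing (a deliberate replacement
for an external packing tool) and L-BFGS minimization (with a stiff
harmonic penalty standing in for the rigid-water constraints during
descent), 25 ps NVT scramble at 500 K under Berendsen, 100 ps NpT at
the target temperature, a short Langevin damping stage for acoustic
shocks, then NVT production under Nosé–Hoover.  All durations and
couplings are configurable; the defaults are the published ones.

## Analyses

- **RDF**: shell-volume/ideal-density normalized histogram of
  minimum-image distances, default 1 pm bins, intramolecular pairs
  excluded.  The normalization satisfies the exact counting identity
  ∫4πr²ρ g dr = mean counted partners per observer (tested).
- **First peak / first minimum**: moving-average smoothing (3 bins,
  never stored) plus a prominence criterion so shot noise in
  near-empty small-r shells is not mistaken for a contact peak.
- **Coordination number**: n = 4πρ∫g r² dr to the first minimum,
  integrated bin-wise (rectangle rule with a fractional final bin),
  which reproduces the underlying pair counts exactly.
- **Distance–angle CDF**: 2D histogram over the H⋯acceptor distance
  and the deviation from donor–H⋯acceptor linearity (0° = linear).
- **SDF**: target density on a 3D grid in a molecule-fixed orthonormal
  frame built from three non-collinear anchor atoms; reported in nm⁻³;
  the grid integral equals the mean target count (conservation test).
- **Hydrogen-bond lifetimes** from the population operator h(t) under
  a geometric criterion (defaults r(H⋯O) ≤ 300 pm, deviation ≤ 30°,
  chosen to bracket the main contact peak of carboxylate⋯ring-proton
  bonds; the published study's exact per-pair criteria live in an
  appendix not reproduced here, so both cutoffs are configurable).
  The *intermittent* lifetime integrates ⟨h(0)h(t)⟩/⟨h⟩ (breaking and
  re-forming allowed); the *continuous* lifetime integrates the
  survival function of the unbroken bond.  Both integrals add a
  single-exponential tail fitted to the last third of the sampled
  window, because real lifetimes (hundreds of ps) can exceed any
  affordable trajectory; censoring (bonds alive at the trajectory
  edges) is flagged.  On a memoryless telegraph process the continuous
  estimate equals 1/k_break (tested at rates 0.1–2 ps⁻¹ within 10 %).
  Note that for a two-state fixture with large stationary population
  the intermittent correlation plateaus at ⟨h⟩ and its integral is
  dominated by the tail — in molecular systems the per-pair ⟨h⟩ is
  near zero and the integral is meaningful.
- **Self-diffusion**: Einstein relation D = slope(MSD)/6 on unwrapped
  coordinates, all time origins (FFT algorithm), lags ≤ 50 % of the
  trajectory, default fit window 10–50 % of the maximum lag.  Brownian
  fixtures with known D are recovered within 10 %.

## Synthetic data

`bilff.fixtures` generates seeded trajectories with known statistical
structure (ideal gas, frozen pair, telegraph hydrogen bond, Brownian
walkers, Gaussian shell).  They exercise every analysis estimator
against closed-form answers, but they contain none of the correlations
of a real liquid — no excluded volume, no momentum conservation, no
coupling between structure and dynamics.  Passing those tests shows
the *estimators* are correct, not that the force field reproduces any
particular liquid.  The latter is probed separately by the reduced
molecular-dynamics runs below.

## Problem sizes and reduced-scale runs

The published parameterization used 128 ion-pair boxes and 10 ns of
production — cluster-scale work.  This package's self-contained runs
use reduced systems chosen to keep a complete pipeline within desk
scale: 6–8 ion pairs of [EMTr][OBz] (the one ion pair whose parameters
are fully printed and embedded), optionally with water at the 1:3
molar ratio, ~15 Å boxes, a few ps per protocol stage, and a ~7 Å
cutoff (hence the LJ tail correction in NpT).  At this scale the
hydrogen-bond contact structure (first RDF peak near 200 pm) forms
within picoseconds, but peak heights, coordination numbers, NpT
densities and especially lifetimes carry finite-size and
finite-sampling scatter of tens of percent, and slow intermittent
lifetimes are tail-extrapolation dominated.  Acetate- and
imidazolium-containing systems additionally require a user-supplied
parameter file (see above) and are not part of the self-contained
runs.

## Known limitations

- No polarizability; charge scaling is the model's substitute.
- No improper torsions (none are published for these ions); aromatic
  planarity is maintained by the large V₂ proper terms.
- Ewald instead of PPPM: correct but O(N^{3/2}); practical to a few
  hundred atoms, not thousands.
- The barostat neglects the rigid-water constraint virial and scales
  atomic (not molecular) coordinates, re-projecting water by SHAKE.
- Random-insertion packing cannot reach liquid density directly;
  boxes are packed ~25 % oversized and compressed by the NpT stage.
- `first_peak` assumes a reasonably sampled RDF; with very few frames
  the prominence filter may reject a genuine but noisy peak.
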