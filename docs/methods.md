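# Methods

## Constant-force pulling in Cartesian coordinates

The engine minimizes the force-modified surface
`E_eff(x) = E(x) − f·d(x)`, where `d` is the distance between the two
anchor atoms and `f ≥ 0` is the force magnitude in atomic units
(Hartree/Bohr; 1 au = 82.387 nN, displayed at two decimals as 82.39).
The gradient of the external term is exactly the equal-opposite-collinear
force pair (+f·û on one anchor, −f·û on the other, û the unit vector
between them), so the pair exerts zero net force and zero net torque and
the modified surface remains translation- and rotation-invariant.  The
definition is Cartesian throughout; no internal-coordinate transformation
is involved, and the same `f` may be interpreted as the quasi-static load
of a pulling experiment.

Minimization is quasi-Newton (BFGS on the inverse Hessian) with an
Armijo backtracking line search, so `E_eff` is non-increasing along
accepted cycles, and a per-cycle trust cap of 0.3 Å on the largest
displacement component.  Every accepted cycle is recorded — backbone
energy `E`, effective energy `E_eff`, anchor distance, max gradient, and
(optionally) the full frame — because the *history* of an enforced
optimization carries mechanistic information: barrier crossings appear
as interior energy maxima/minima along the cycle axis.  Cycle counts are
optimizer-specific; analyses of histories should rely on the landmark
*topology* (number and order of extrema, relative barrier heights), not
on absolute cycle numbers.

Convergence uses the standard compound criterion of molecular geometry
optimizers: max gradient ≤ 4.5·10⁻⁴ au and rms gradient ≤ 3·10⁻⁴ au,
plus either max displacement ≤ 1.8·10⁻³ Å or energy change ≤ 10⁻⁶
Hartree.  A line search that cannot move at a point already satisfying
the gradient criteria counts as converged (the displacement is
effectively zero).  All tolerances are configurable (`EGOOptions`).

**Rupture** is an observable, not a model event: whenever a bonded pair
exceeds 2.0 × its reference length (the backend's equilibrium length
when available, else the starting length) a rupture event is logged with
the bond, cycle and length, and the optimization continues.  On the
harmonic toy backend bonds never literally dissociate, so the factor is
the operational definition of breakage.

**Vibrational stability** builds the Hessian from central differences of
the analytic gradient (step 10⁻³ Å), mass-weights it, projects out the
rigid-body subspace (6 modes, 5 for linear molecules, identified by an
SVD of the mass-weighted translation/rotation vectors), and reports the
lowest nontrivial frequency and the count of negative-curvature modes.
It refuses structures whose gradient is not near-stationary.

## Ring puckering and conformer labels

Ring atoms are ordered O5, C1, …, C5 (IUPAC torsion convention), which
places the ⁴C₁ chair of a D-pyranose at θ = 0°.  Displacements from the
puckering mean plane condense into (q₂, φ₂) and q₃, with
Q² = q₂² + q₃², tan θ = q₂/q₃.  Rings with Q below 0.05 Å are reported
planar, with no phase angles and no label.

The canonical table holds the full 38-conformer itinerary: 2 chairs, 6
boats and 6 twist-boats on the equator (every 30° in φ), 12 envelopes
(θ ≈ 54.7°/125.3°) and 12 half-chairs (θ ≈ 50.8°/129.2°).  Equator label
positions were derived analytically from the inverse puckering
construction (e.g. ¹,⁴B at φ = 240°, ⁵S₁ at 90°, ²S_O at 150°,
ᴼS₂ at 330°).  Classification is nearest-canonical by great-circle
distance on the (θ, φ) sphere; exact ties break toward lower θ, then
lower φ (so a point equidistant between a skew and its neighbouring boat
labels as the lower-φ conformer, deterministically).

A second route fits the six endocyclic torsions by least squares in the
three-member ideal basis {¹C₄-type, ¹,⁴B-type, ᴼS₂-type}, whose members
span the pucker space (one polar, two equatorial 90° apart in φ); the
coefficients map back to an effective (θ, φ) that is classified the same
way.  The two routes agree everywhere except within a ≈10° band around
classification boundaries, where the mild nonlinearity of torsions in
the pucker amplitude can move a point across the border; tests therefore
require agreement only when the margin between the nearest and
second-nearest canonical conformer exceeds 10°.

The coarse **length bins** label a unit by its flanking O–O distance:
nearest of c = 4.5, b1 = 4.3, b2 = 5.1, ic = 5.5 Å within ±0.25 Å, else
"unassigned"; exact ties go to the lower-energy conformer (chair first).
Length bins conflate ring pucker with exocyclic bond orientation, so the
pucker-based classification is primary and the bins are a cross-check.

## The toy energy backend

The built-in backend is a deliberately small valence force field:
harmonic bonds (k ≈ 0.75–1.9 Ha/Å² by element pair) and angles
(0.30 Ha/rad², θ₀ by centre coordination), a generic three-fold cosine
torsion (0.0015 Ha), a soft quadratic nonbonded repulsion
(ε = 0.01 Ha, σ = 2.5 Å, pairs ≥ 4 bonds apart), and a dedicated
two-term endocyclic torsion profile
`c₃(1 + cos 3τ) + c₁(1 + cos τ)` with c₃ = 0.002, c₁ = 0.001 Ha.  The
three-fold term builds the staggered wells that make chairs minima, the
one-fold term penalizes eclipsed arrangements, and the stiffness balance
(angles stiff relative to ring torsions) was chosen so that pulling the
anchors destabilizes the chair basin rather than being absorbed by angle
bending — the condition for force-driven ring inversion to occur at all
on a local-minimization surface.  Parameters ship in a versioned
defaults file (`egostretch/data/toyff-1.yaml`); analytic gradients match
central finite differences to < 10⁻⁸ Ha/Bohr.

With these defaults the anchored toy ring has three stationary basins
(⁴C₁ global minimum, an equatorial boat/twist-boat band, ¹C₄), inverts
permanently above ≈ 0.086 au, and transits the equator (θ through 90°)
on the way — the chair → twist-boat → inverted-chair mechanism — with
chain elongation saturating before the flip.  The 23-atom monomer
inverts near 0.17 au, passing through a ²S_O stage.  These thresholds
are properties of the toy surface; quantum backends put them elsewhere,
and no claim is made that toy forces, energies or barriers are
thermochemically meaningful.  The backend contract
(`evaluate(coords) → (E, ∇E)`, stateless per call) is the only coupling
point, so a quantum-chemistry adapter can replace the toy model without
touching the protocol.

## The synthetic generator

The generator emulates the pipeline's inputs instead of downloading
them: ideal six-rings at arbitrary (Q, θ, φ), galacturonic-acid-like
monomers, and (1→4)-linked oligomers.

* **Ring construction** solves a small least-squares system — six exact
  bond lengths plus the three puckering components — from a
  regular-hexagon initial guess; round-trip recovery of (Q, θ, φ) is
  ≤ 10⁻⁶.  Infeasible amplitudes raise.
* **Amplitudes** default per conformer class: 0.57 Å for chairs (typical
  of pyranoses), 0.75 Å for the equator (boats/twist-boats relieve angle
  strain at visibly larger amplitude), 0.65 Å for envelopes/half-chairs.
* **Monomers** use standard bond lengths (C–C 1.52, ring C–O 1.43,
  hydroxyl C–O 1.42, C=O 1.21, O–H 0.97, C–H 1.10 Å) and tetrahedral
  substituent placement.  Stereochemistry is the galacto configuration —
  O1 and O4 axial in ⁴C₁, O2/O3 equatorial, carboxyl equatorial —
  calibrated once on the ⁴C₁ reference ring and conserved across
  conformers (axial/equatorial character then follows from the ring
  geometry, as it must).  The resulting anchor-oxygen distances are
  4.43 Å (⁴C₁), 5.50 Å (¹C₄), 5.01 Å (²S_O) and 4.38 Å (⁵S₁), inside the
  characteristic c/ic/b2/b1 bands.
* **A minimal anchored ring** (ring + anchor O and blocking H at C1/C4,
  10 atoms) carries exactly the mechanical degrees of freedom the
  pulling experiment exercises.  The hydrogens are essential: without a
  substituent in the second tetrahedral slot the anchor C–O bond can
  swing from axial to equatorial through the vacancy and no torque
  reaches the ring.
* **Oligomers** chain monomers through C1–O–C4′ linkages (one water
  condensed per linkage; 23n − 3(n−1) atoms), placing each new unit by
  internal-coordinate construction so the requested glycosidic dihedrals
  are built exactly (φ = H1–C1–Og–C4′, ψ = C1–Og–C4′–H4′, the
  conventional quadruples; any user-specified quadruples are recorded
  verbatim by the measurement API).  Defaults φ = 20°, ψ = −20° give an
  extended, clash-free helix-like chain (hexamer anchor span ≈ 25.8 Å);
  they are the generator's own choice of a reasonable starting helix,
  not a fit to any particular crystal structure.  Builds whose requested
  dihedrals collide below 1.0 Å (non-bonded, > 3 bonds apart) retry with
  small uniform dihedral offsets and warn; unresolvable clashes raise
  with the offending pair.
* **Anionic units** are formal-charge bookkeeping only (carboxyl proton
  removed, charge −1); the toy backend has no electrostatics, so their
  energetics are untested by design.
* All randomness (perturbations) flows through explicit integer seeds.

What passing tests on these fixtures do *not* show: real sugars have
anomeric effects, hydrogen-bond networks, solvent and electrostatics,
none of which the toy surface contains; agreement of the pipeline's
*mechanics* (classification, protocol logic, curve analysis) with
constructed ground truth says nothing about quantum-level force
thresholds or energies.

## The protocol

Scans follow the stretch–relax discipline: relax the input once at
f = 0; for each ladder force *ascending, starting from that same relaxed
reference* (not chained from the previous force — chaining is a
different experiment), stretch, relax, classify every unit.  A
"permanent" change means the relaxed label vector differs from the
start.  Records are kept even for unconverged points (flagged);
backend failures flag the record and the scan continues.  Regions are
maximal constant-label intervals below the first rupture, and the
minimal transition force is refined by bisection between the last
non-transitioning and first transitioning force down to
`refine_resolution`, reporting the bracket midpoint; a ladder already
transitioning at its floor reports "unbracketed", a ladder with no
transition reports "absent" (neither is an error).

**Plateau detection** is necessarily an operational definition: a
maximal run of curve segments whose extension jump is ≥ 0.3 Å per ladder
step (configurable) with total force advance within 2 ladder steps.  The
per-step formulation separates transition jumps from ordinary elastic
slope, which on the toy backend is itself substantial (~0.17 Å per
0.01 au).  Plateau spans may share a boundary point but never overlap.

**History landmarks** are interior extrema of the backbone energy after
a centred moving average (window 3 by default; window 1 = raw extrema;
flat segments inherit the preceding slope so alternation is guaranteed);
each barrier is the rise from the preceding landmark (or series start)
to the maximum, and the first-vs-second barrier comparison is exposed as
a computed predicate.

## Numerical and scope notes

* Internal units: Å, Hartree, Hartree/Bohr; all conversion factors live
  in `egostretch.units`.  The force conversion constant is the
  CODATA-derived 82.387 nN/au, rounded to two decimals only for display.
* XYZ is written at 10 decimals (round-trips to 10⁻⁴ Å and better); PDB
  fixes three decimals, so its round-trip precision is 5·10⁻⁴ Å.  Readers
  reject malformed records (inconsistent atom counts, unknown elements)
  rather than repairing them.  Bonds absent from a format are inferred at
  1.3 × the sum of covalent radii; PDB CONECT records take precedence.
* Everything is deterministic: identical inputs give bit-identical
  traces on one platform; scans and searches use no global random state.
* Test and acceptance problem sizes — the 10-atom anchored ring for
  scans, the 23-atom monomer for fixtures, ladders of ≤ 15 forces — are
  the package's choice of desk-scale defaults; larger systems run through
  the identical code paths.
* Out of scope: transition-state searches from maximum-energy cycles,
  thermal/dynamic sampling, polymer-elasticity (worm-like-chain) fits,
  electronic structure itself, esterification/branching chemistry.
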