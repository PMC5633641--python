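# Methods

This note records the models implemented in mmkit, the defaults and why
they were chosen, the numerical decisions that affect results, what the
synthetic fixtures do and do not emulate, and the known limitations.

## Units and conventions

Internally: Å, kcal/mol, elementary charges, amu, fs, radians (degrees at
all file and CLI interfaces). Coulomb constant 332.0636 kcal·Å/(mol·e²);
k_B = 0.0019872041 kcal/(mol·K); the acceleration conversion is
a [Å/fs²] = F [kcal/mol/Å] / m [amu] × 4.184·10⁻⁴. Dihedrals follow the
IUPAC sign convention (cis = 0°, range (−180°, 180°]); note that the
dihedral is *invariant* under reversing the four atoms — antisymmetry holds
only under mirror reflection.

## Force field

The energy is the AMBER/GAFF functional form. Bonds and angles are harmonic
with the force constant absorbing the conventional ½ (`E = k(x − x₀)²`), so
a printed k of 310 kcal/mol/Ų corresponds to an AMBER K_r of 310. Torsion
terms are `(Vₙ/2)(1 + cos(nφ − γ))` and may stack several (n, γ) terms per
atom-type quadruple; improper terms use the same form and contribute only
when the parameter set defines them. LJ uses σ/ε with Lorentz–Berthelot
combining. Nonbonded exclusions are 1-2 and 1-3 pairs; 1-4 pairs are scaled
by 1/2.0 (LJ) and 1/1.2 (Coulomb), the AMBER convention.

Electrostatics use the damped-shifted-force form with defaults R_c = 9 Å
and α = 0.2 Å⁻¹ — values from the DSF literature's commonly used range; the
method's defining property is that both E and dE/dr vanish at R_c, so the
truncation introduces no force discontinuity. The 1-4 Coulomb term applies
the same DSF form scaled by 1/1.2, keeping the total energy a single smooth
function (classic AMBER scales plain 1/r there; at these distances the two
differ by the smooth shift terms only). LJ is plainly truncated at the same
cutoff with no energy shift: pair energies at 9 Å are ~10⁻⁴ ε, and the
energy-conservation tests choose fixtures whose pairs do not cross the
cutoff. A deliberate consequence of truncation by *atom pair* here versus
*charge group* in the crystal module is that the two electrostatic paths
are not interchangeable.

Nonbonded evaluation is an O(N²) vectorised pair loop — the reference
implementation for desk-scale systems (hundreds of atoms); no neighbour
list is built.

Atom typing is by element, with one refinement: hydrogens bonded to N or O
get type `HP`, which carries zero LJ parameters. Without this (the AMBER
convention for polar hydrogens) hydrogen bonding is sterically impossible,
and the hydroxyl-orientation optimiser could never point an O–H at an
acceptor.

### Charge assignment

The built-in scheme is a one-shot electronegativity equalisation over
bonds: `q_i = κ Σ_j (χ_j − χ_i)` over bonded neighbours with Pauling
electronegativities and κ = 0.16 e per Pauling unit (chosen so water gets
q_H ≈ +0.20 e, the right order for fixed-charge force fields), followed by
a uniform per-charge-group shift so each group sums exactly to its formal
charge (±1 for Lys/Arg/Asp/Glu side chains, 0 otherwise). It is a
structural stand-in with correct symmetry and neutrality properties, not a
fit to any quantum-mechanical reference.

## Minimisation

Two optimisers share an interface over flat coordinate vectors:

- **L-BFGS** (history m = 10) with Armijo backtracking plus a one-step
  curvature expansion; used by default above 400 atoms.
- **Powell–Beale conjugate gradient**: Hestenes–Stiefel β, Powell's
  loss-of-conjugacy restart test |g_{k+1}·g_k| ≥ 0.2 |g_{k+1}|², and
  Beale's three-term recurrence using the restart direction — the third
  term is suppressed on the first step after a restart, where it would
  duplicate the β term. The line search brackets by expansion and then
  zooms with safeguarded secant steps on φ′(α) (exact after one step on a
  quadratic, which yields the classical ≤ n-step termination on convex
  quadratics); the safeguard falls back to bisection when the secant step
  lands within 5% of a bracket end, which matters on the non-unimodal
  profiles LJ walls produce.

Convergence is declared on the **mean per-atom gradient norm** over free
atoms (default 0.5 (kcal/mol)/Å); an RMS variant is selectable via
`grad_measure="rms"`. Frozen atoms are excluded from the measure and their
coordinates are returned bit-identical to the input; partial optimisation
of a complex freezes every protein atom outside the flexible selection.
Accepted steps never increase the energy; a failed line search returns a
diagnostic non-converged result rather than raising.

## Dynamics

Velocity Verlet; ndof = 3N − 3 after centre-of-mass momentum removal at
start-up; no constraint algorithms, so the time step must resolve the
stiffest bond (≈ 0.5 fs for X–H with these parameters, 1–2 fs for
heavy-atom-only systems; default dt = 1 fs). The Berendsen thermostat
rescales velocities after the update by λ = sqrt(1 + (dt/τ)(T₀/T − 1)),
default τ = 100 fs; τ = ∞ reproduces the unthermostatted trajectory
bitwise. Periodic boxes are orthorhombic with minimum-image distances
applied to nonbonded pairs only (bonded terms assume whole molecules).
Initial velocities are Maxwell–Boltzmann draws, deterministic under the
seed. Berendsen coupling controls the mean temperature but suppresses
kinetic-energy fluctuations; it does not sample a canonical ensemble.

## Crystal lattice sums

Cells are described by (a, b, c, α, β, γ) with the basis matrix built
a-along-x, b-in-xy. The lattice energy per cell is the full force-field
energy of the cell contents plus half the sum of LJ + plain-Coulomb
interactions between the central cell and the 124 images of the 5×5×5
grid. Electrostatic truncation acts on **neutral charge groups** (default:
one group per residue): a pair of groups is included whole, or not at all,
by the distance between group geometric centres against the nonbonded
cutoff. Because each group is neutral, the leading truncated multipole is
dipole–dipole (r⁻³), and the 5×5×5 sum is a usable approximation without
Ewald summation. LJ uses the same group gating so the inter-image sum has
one inclusion rule. Non-neutral groups are refused (overridable with a
warning).

Optimisation treats fractional coordinates plus, optionally, the six cell
parameters as one variable vector, minimised with the CG method; all
gradients here are central finite differences (h = 10⁻⁴ relative), which is
simpler than analytic strain derivatives and adequate at desk scale. Cells
whose volume falls below 20% of the starting volume abort with a
diagnostic; trial cells outside (0.05 Å, 179°) bounds evaluate to +∞ so the
line search retreats. Space groups are explicit operator lists (P1
default); symmetry is applied at expansion time and not constrained during
optimisation.

## Statistical pair potentials

`pmf_from_histogram` Boltzmann-inverts a binned distance distribution
against either an explicit reference histogram or the DFIRE-style
distance-scaled reference g_ref ∝ r^s with s = 1.61 (the exponent is a
parameter; 1.61 follows the cited convention for that family). Defaults:
0.2 Å bins, 12 Å cutoff, T = 300 K, zero-count bins capped at +3 kcal/mol.
Energies are shifted so the last bin inside the cutoff is zero — this
anchoring means *absolute* table values are only defined up to that
convention (a single-bin table is identically zero); differences between
bins are the physical content. Pose scores interpolate linearly between
bin centres, clamp below the first centre, and are exactly zero at and
beyond the cutoff; only receptor–ligand (inter-selection) pairs are
counted, never intra-ligand pairs. Atom typing for scoring is pluggable;
the shipped minimal typing is element-based with polar hydrogens split out.

Three-point alignment builds a right-handed orthonormal frame on each
triplet (x along 1→2, z normal to the 1-2-3 plane) and applies the frame
rotation plus the point-1 translation; this realises translate-then-two-
rotations exactly and is idempotent.

## Rotamers, hydrogens, surfaces

The three-state rotamer library is the Cartesian product of
{−60°, +60°, 180°} over each residue's rotatable χ bonds (Gly/Ala/Pro have
none, Lys/Arg four → 1…81 rotamers). External libraries load from a
one-rotamer-per-line text format. Scans enumerate the full product over up
to six residues (a guard refuses > 10⁶ combinations), apply each
combination through the torsion editor, score it against the rest of the
structure **including scan-residue↔scan-residue pairs**, keep the best ten
by stable ascending sort (enumeration order breaks ties), and optionally
append force-field rescoring without reordering.

Residue mutation keeps N/CA/C/O fixed and rebuilds the side chain from
idealised internal-coordinate templates (Engh–Huber-style consensus bond
lengths and angles; the CB branch dihedral +122.5° gives L-configuration)
at the library's first rotamer (gauche− for every χ).

Hydrogen placement is residue-template-driven for amino acids (per-atom H
counts and sp²/sp³ geometry; His defaults to the ε-protonated tautomer,
with δ- and doubly-protonated variants available) and heuristic for other
residues (carbonyl oxygens and planar 5/6-rings treated as sp²; ring
nitrogens are skipped and reported, since pyridine- vs pyrrole-type
nitrogens cannot be distinguished without bond orders). Polar-hydrogen
optimisation grid-searches Ser/Thr/Tyr hydroxyl torsions in 10° steps on
the force-field energy, evaluates Asn/Gln/His terminal-group flips as 180°
torsion rotations, and sweeps sites to convergence (≤ 10 sweeps);
degenerate sites (spread < 10⁻⁶ kcal/mol) keep their input state and are
flagged.

SASA is Shrake–Rupley sphere sampling on a deterministic golden-spiral
point set (default 960 points, 1.4 Å probe, Bondi-style radii); accuracy is
~0.1–1% and rigid-motion invariance is limited to the same order by the
fixed quadrature. PSA sums the accessible area of N, O and hydrogens
bonded to them.

## Z-matrix machinery

Conversion to Cartesians uses NeRF placement with the frame convention
origin / +x / +xy(+y). Conversion from Cartesians picks, per atom, the
nearest previously defined reference atoms that give a non-degenerate angle
(bonded atoms preferred for the bond reference); geometries with an
unavoidable collinear reference (e.g. a linear triatomic) raise a
degenerate-geometry error rather than producing an ill-conditioned row.
Round trips reproduce geometry to < 10⁻⁸ Å RMSD (in practice ~10⁻¹⁴).
Torsion editing rotates the smaller of the two components separated by the
central bond (ties: the far side), preserving all intra-component
distances exactly; bonds in rings are refused.

Ramachandran classification is point-in-polygon against coarse two-tier
general-case regions (α and β cores plus expanded margins and the
left-handed α region). The polygons are deliberately simple convex
outlines adequate for flagging outliers; no agreement with any specific
published contour set is claimed.

## Synthetic fixtures: what they do and do not show

All test inputs are generated in code. The toy parameter set covers
{H, HP, C, N, O, S} with physically plausible constants (bond r₀ within
0.9–1.9 Å, angles 99–112°, single wildcard torsion); it exercises every
code path of the real functional form but is **not** fit to reproduce real
molecular energetics — carbonyl C=O, for instance, shares the single C–O
bond parameter. Polyalanine peptides are built at ideal geometry with
chosen (φ, ψ); the toy pocket is a rigid 12-atom LJ cage with a diatomic
ligand placed off its interior minimum; toy crystals are one LJ atom or one
bonded ionic dipole per cubic P1 cell. Distance histograms come from a
Metropolis chain on p(r) ∝ r² exp(−U/k_BT) that mixes local Gaussian moves
with global uniform proposals — the mixture makes successive samples nearly
independent, so per-bin counting noise is the right error model for
recovery tests. Passing tests therefore demonstrate correctness of the
*algorithms* (gradients, sums, enumeration, conversions, truncation
contracts) at small scale, not force-field accuracy, sampling quality on
real proteins, or performance at protein-database scale.

The rigid-receptor/flexible-ligand optimisation protocol (loose 0.5 and
tight 0.1 (kcal/mol)/Å tolerances, heavy-atom RMSD reported) is reproduced
on the toy pocket; validating it against experimental protein–ligand
complexes requires real force-field parameter files and curated structures,
which are outside this package's self-contained scope.

## Problem sizes

Defaults used by the tests and the acceptance script: peptides of 1–5
residues (13–53 atoms), a 64-particle LJ fluid for thermostat checks
(3000 × 2 fs), 1000-step drift runs, 150 000-sample histograms, 81-rotamer
scans, ≤ 4-atom crystal cells. These sizes make every check exhaustive
(brute-force oracles included) while keeping the full suite under a minute
of compute for the numerical core.

## Known limitations

No Ewald/PME (the neutral-group 5×5×5 sum is the crystal-scale
approximation); no neighbour lists (O(N²) pairs); no constraint algorithms
(SHAKE) and hence small MD time steps; orthorhombic boxes only; no
backbone-dependent rotamer probabilities; insertion/deletion with loop
closure is not implemented; the charge scheme is a structural stand-in; PDB
support covers the ATOM/HETATM/TER/CONECT/CRYST1 subset (no mmCIF).
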