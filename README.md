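# mmkit

A scriptable molecular-mechanics toolkit for structural bioinformatics:
force-field energies and exact analytic gradients with damped-shifted-force
electrostatics, energy minimisation, molecular dynamics, crystal lattice
sums, knowledge-based pose scoring, rotamer-space scanning, protein editing
in internal coordinates, hydrogen placement and surface areas — everything a
desk-scale modelling workflow needs, usable from Python or from a thin CLI.

It is aimed at people who prepare, relax and probe protein and small-molecule
structures: mutate a residue and scan its side-chain rotamers, dock a ligand
by scripted rigid moves and score each pose, relax a complex with the
receptor held rigid, run a short thermostatted trajectory, or optimise a
small-molecule crystal including its cell parameters.

## The models

**Force field.** The AMBER/GAFF functional form: harmonic bonds and angles
`E = k (x − x₀)²`, periodic torsions `E = Σ (Vₙ/2)(1 + cos(nφ − γ))`, 12-6
Lennard-Jones with Lorentz–Berthelot combining, and 1-4 pairs scaled by
1/2.0 (LJ) and 1/1.2 (Coulomb). Electrostatics use the damped-shifted-force
(DSF) scheme,

```
E(r) = C q₁q₂ [ erfc(αr)/r − erfc(αR_c)/R_c
                + (erfc(αR_c)/R_c² + (2α/√π) e^{−α²R_c²}/R_c)(r − R_c) ],
```

which vanishes *together with its derivative* at the cutoff R_c, so the
truncated sum is smooth without lattice summation (defaults R_c = 9 Å,
α = 0.2 Å⁻¹). Gradients of every term are exact analytic derivatives,
verified against central finite differences in the test suite.

**Minimisation.** Limited-memory BFGS for protein-sized systems and a
Powell–Beale restarted conjugate gradient for small molecules, both with
atom freezing (rigid-receptor partial optimisation) and convergence on the
mean per-atom gradient norm, default 0.5 (kcal/mol)/Å.

**Dynamics.** Velocity Verlet with the Berendsen weak-coupling thermostat,
`λ = sqrt(1 + (dt/τ)(T₀/T − 1))`, optional orthorhombic periodic box with
minimum-image distances.

**Crystals.** The infinite crystal is approximated by a 5×5×5 supercell
(125 cells); inter-image electrostatics are truncated on *neutral charge
groups* — a pair of groups enters the sum whole or not at all, decided by
group-centre distance — which converges without Ewald machinery. Geometry
and the six cell parameters are optimised jointly.

**Knowledge-based scoring.** Pair potentials from Boltzmann inversion,
`e(r) = −k_B T ln(g_obs/g_ref)`, with either an explicit bulk reference or
the DFIRE-style distance-scaled reference `g_ref ∝ r^1.61`; pose scores are
sums of interpolated table lookups over receptor–ligand pairs with a
per-pair decomposition. Rotamer scans enumerate the three-state
(gauche−/gauche+/trans) χ product — 1 rotamer for Gly/Ala up to 81 for
Lys — for up to six residues, keep the best ten, and can rescore with the
force field.

## A worked example

`examples/03_crystal_optimisation.py` optimises the lattice constant of a
one-atom Lennard-Jones crystal against the 125-cell supercell sum:

```
start:   a = 4.200 A, lattice energy = -0.2975 kcal/mol
1-D scan optimum: a* = 3.640 A (E = -0.4654 kcal/mol)
optimised: a = 3.643 A, E = -0.4654 kcal/mol, converged = True
```

The optimiser recovers the independently scanned optimum to 0.1%. The other
scripts in `examples/` each demonstrate one capability — minimisation,
thermostatted MD (mean T 119.7 K against a 120 K target), pose scoring with
ligand moves, a two-residue rotamer scan with force-field rescoring, protein
editing via torsions/mutation/Ramachandran classification, and SASA/PSA
(methane 0 Ų polar; water entirely polar).

There is also a CLI with the same functionality:

```
mmkit fixtures polyala --n 5 --out pep.pdb
mmkit optimize pep.pdb --tol 0.5 --out pep_opt.pdb
mmkit rotamer-scan pep.pdb --residues 3 --out scan.tsv
mmkit md pep.pdb --steps 1000 --temperature 300 --log md.tsv
```

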