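"""Deterministic generators for self-contained test inputs.

Everything needed to exercise the engines is generated in code: a toy
force-field parameter set over the elements {H, C, N, O, S}, ideal-geometry
polyalanine peptides, a rigid Lennard-Jones pocket with a flexible ligand,
single-atom and ionic-diatomic toy crystals, and Boltzmann-sampled distance
histograms for pair-potential inversion.  Identical arguments (including the
seed) always produce bitwise-identical fixtures; each generator validates its
output before returning.

The toy parameters are physically plausible (bond lengths 0.9-1.9 A, angles
100-130 degrees) but make no claim of force-field accuracy.
"""

from __future__ import annotations

import math

import numpy as np

from .crystal import CrystalSystem, UnitCell, lattice_energy
from .dynamics import KB
from .forcefield import (AngleParam, BondParam, LJParam, NonbondedSettings,
                         ParameterSet, TorsionParam, assign_simple_charges,
                         energy_and_gradient)
from .internal_coords import mutate_residue, place_by_internal
from .molsys import (Atom, MolecularSystem, Residue, Topology,
                     perceive_topology)
from .scoring import DistanceHistogram
from .structure_tools import place_missing_hydrogens, sphere_points

__all__ = [
    "make_toy_paramset", "make_polyala", "make_toy_pocket", "make_toy_crystal",
    "make_synthetic_histograms",
]


def make_toy_paramset() -> ParameterSet:
    """Complete element-typed parameters for {H, C, N, O, S}.

    Atom types are element symbols; angle and torsion terms use wildcard
    keys so every bonded term of any generated fixture resolves.
    """
    ps = ParameterSet()
    bond_data = {
        ("C", "C"): (310.0, 1.526), ("C", "H"): (340.0, 1.090),
        ("C", "N"): (337.0, 1.449), ("C", "O"): (320.0, 1.364),
        ("C", "S"): (227.0, 1.810), ("N", "H"): (434.0, 1.010),
        ("O", "H"): (553.0, 0.960), ("S", "H"): (274.0, 1.340),
        ("N", "N"): (350.0, 1.400), ("N", "O"): (300.0, 1.400),
        ("O", "O"): (300.0, 1.450), ("S", "S"): (166.0, 1.900),
        ("N", "S"): (250.0, 1.700), ("O", "S"): (250.0, 1.700),
        ("H", "H"): (100.0, 0.740),
    }
    for key, (k, r0) in bond_data.items():
        ps.bonds[key] = BondParam(k, r0)
    # polar hydrogens (type HP) share H bonded geometry but carry no LJ volume
    for heavy, hkey in (("N", ("N", "HP")), ("O", ("O", "HP")), ("S", ("S", "HP")),
                        ("C", ("C", "HP")), ("H", ("H", "HP"))):
        ps.bonds[hkey] = ps.bonds[(heavy, "H")]
    for centre, (k, th0) in {"C": (55.0, 111.0), "N": (70.0, 112.0),
                             "O": (60.0, 104.5), "S": (62.0, 99.0),
                             "H": (35.0, 110.0)}.items():
        ps.angles[("X", centre, "X")] = AngleParam(k, math.radians(th0))
    ps.torsions[("X", "X", "X", "X")] = TorsionParam(((0.30, 3, 0.0),))
    lj_data = {"H": (2.50, 0.016), "HP": (0.0, 0.0), "C": (3.40, 0.086),
               "N": (3.25, 0.170), "O": (3.00, 0.210), "S": (3.60, 0.250)}
    for t, (s, e) in lj_data.items():
        ps.lj[t] = LJParam(s, e)
    return ps


# ideal backbone geometry (A / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.6, 121.9, 120.8
_OMEGA = 180.0

_CONFORMATIONS = {"helix": (-60.0, -45.0), "extended": (-180.0, 180.0)}


def make_polyala(n_residues: int, conformation: str = "helix") -> MolecularSystem:
    """Chemically complete polyalanine with ideal geometry.

    Backbone torsions are set to (phi, psi) = (-60, -45) for ``helix`` or
    (-180, 180) for ``extended``; the chain carries a free-amine N terminus
    and a protonated carboxyl C terminus, with all hydrogens placed.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    phi, psi = _CONFORMATIONS[conformation]
    system = MolecularSystem()

    def add_atom(name: str, element: str, pos: np.ndarray, ridx: int) -> int:
        idx = len(system.atoms)
        system.atoms.append(Atom(serial=idx + 1, name=name, element=element,
                                 pos=np.asarray(pos, float), residue_index=ridx))
        system.residues[ridx].atom_indices.append(idx)
        return idx

    prev = {}
    for r in range(n_residues):
        system.residues.append(Residue(name="ALA", chain="A", seqnum=r + 1,
                                       kind="amino"))
        if r == 0:
            n = add_atom("N", "N", [0.0, 0.0, 0.0], r)
            ca = add_atom("CA", "C", [_B_N_CA, 0.0, 0.0], r)
            th = math.radians(_A_N_CA_C)
            c = add_atom("CA_C", "C", system.atoms[ca].pos +
                         _B_CA_C * np.array([-math.cos(th), math.sin(th), 0.0]), r)
            system.atoms[c].name = "C"
        else:
            n = add_atom("N", "N", place_by_internal(
                system.atoms[prev["N"]].pos, system.atoms[prev["CA"]].pos,
                system.atoms[prev["C"]].pos, _B_C_N, _A_CA_C_N, psi), r)
            ca = add_atom("CA", "C", place_by_internal(
                system.atoms[prev["CA"]].pos, system.atoms[prev["C"]].pos,
                system.atoms[n].pos, _B_N_CA, _A_C_N_CA, _OMEGA), r)
            c = add_atom("C", "C", place_by_internal(
                system.atoms[prev["C"]].pos, system.atoms[n].pos,
                system.atoms[ca].pos, _B_CA_C, _A_N_CA_C, phi), r)
            system.add_bond(prev["C"], n)
        system.add_bond(n, ca)
        system.add_bond(ca, c)
        # carbonyl O anti to the next amide nitrogen
        o = add_atom("O", "O", place_by_internal(
            system.atoms[n].pos, system.atoms[ca].pos, system.atoms[c].pos,
            _B_C_O, _A_CA_C_O, psi + 180.0), r)
        system.add_bond(c, o)
        if r == n_residues - 1:
            oxt = add_atom("OXT", "O", place_by_internal(
                system.atoms[n].pos, system.atoms[ca].pos, system.atoms[c].pos,
                1.251, _A_CA_C_O, psi), r)
            system.add_bond(c, oxt)
        prev = {"N": n, "CA": ca, "C": c}
    system.default_charge_groups()
    for r in range(n_residues):
        mutate_residue(system, r, "ALA")
    place_missing_hydrogens(system)
    from .forcefield import assign_atom_types
    assign_atom_types(system)
    assign_simple_charges(system)
    system.validate()
    return system


def make_toy_pocket(seed: int = 0) -> tuple[MolecularSystem, list[int], list[int]]:
    """A rigid Lennard-Jones cage with a small flexible ligand off-centre.

    Returns (system, receptor_atom_indices, ligand_atom_indices).  The cage
    is 12 carbon pseudo-atoms on a 4 A sphere whose interior is an energy
    minimum; the ligand is a bonded C-C diatomic displaced from the centre
    so partial optimisation has somewhere to go.
    """
    rng = np.random.default_rng(seed)
    system = MolecularSystem()
    system.residues.append(Residue(name="CAG", chain="A", seqnum=1, kind="ligand"))
    cage = 4.0 * sphere_points(12)
    for k, p in enumerate(cage):
        idx = len(system.atoms)
        system.atoms.append(Atom(serial=idx + 1, name=f"C{k + 1}", element="C",
                                 pos=p, residue_index=0))
        system.residues[0].atom_indices.append(idx)
    receptor = list(range(len(system.atoms)))
    system.residues.append(Residue(name="LIG", chain="A", seqnum=2, kind="ligand"))
    centre = np.array([0.9, 0.4, 0.0]) + 0.1 * rng.standard_normal(3)
    axis = np.array([1.0, 0.0, 0.0])
    lig0 = len(system.atoms)
    for k, sgn in enumerate((-0.5, 0.5)):
        idx = len(system.atoms)
        system.atoms.append(Atom(serial=idx + 1, name=f"CL{k + 1}", element="C",
                                 pos=centre + sgn * 1.526 * axis, residue_index=1,
                                 charge=0.1 if k == 0 else -0.1))
        system.residues[1].atom_indices.append(idx)
    system.add_bond(lig0, lig0 + 1)
    ligand = [lig0, lig0 + 1]
    system.default_charge_groups()
    system.validate()
    rep, _ = energy_and_gradient(system, perceive_topology(system),
                                 make_toy_paramset())
    if not math.isfinite(rep.total):
        raise RuntimeError("toy pocket generated with non-finite energy")
    return system, receptor, ligand


def make_toy_crystal(kind: str = "lj_cubic",
                     scan: bool = True) -> tuple[CrystalSystem, dict]:
    """P1 toy crystals with neutral charge groups.

    ``lj_cubic``: one uncharged carbon per cubic cell; ``diatomic_ionic``:
    a bonded N-O dipole (one neutral charge group) per cubic cell.  The info
    dict carries the optimal lattice constant found by a fresh 1-D scan of
    the 125-cell lattice energy (``scan=False`` skips it).
    """
    system = MolecularSystem()
    system.residues.append(Residue(name="MOL", chain="A", seqnum=1, kind="ligand"))
    if kind == "lj_cubic":
        system.atoms.append(Atom(serial=1, name="C1", element="C",
                                 pos=np.zeros(3), residue_index=0))
        system.residues[0].atom_indices.append(0)
        a0 = 4.2
    elif kind == "diatomic_ionic":
        system.atoms.append(Atom(serial=1, name="N1", element="N",
                                 pos=np.zeros(3), residue_index=0, charge=0.3))
        system.atoms.append(Atom(serial=2, name="O1", element="O",
                                 pos=np.array([1.40, 0.0, 0.0]), residue_index=0,
                                 charge=-0.3))
        system.residues[0].atom_indices = [0, 1]
        system.add_bond(0, 1)
        a0 = 5.0
    else:
        raise ValueError(f"unknown crystal kind {kind!r}")
    system.default_charge_groups()
    system.validate()
    crystal = CrystalSystem(cell=UnitCell(a0, a0, a0), contents=system)
    info: dict = {"kind": kind, "start_a": a0}
    if scan:
        top = perceive_topology(system)
        ps = make_toy_paramset()
        best = None
        for a in np.arange(3.2, 6.01, 0.02):
            trial = CrystalSystem(cell=UnitCell(float(a), float(a), float(a)),
                                  contents=system)
            e = lattice_energy(trial, top, ps, NonbondedSettings()).total
            if best is None or e < best[1]:
                best = (float(a), e)
        info["optimal_a"] = best[0]
        info["optimal_energy"] = best[1]
    return crystal, info


def make_synthetic_histograms(potential, n_samples: int = 20000, seed: int = 0,
                              r_min: float = 1.0, r_max: float = 8.0,
                              n_bins: int = 35, T: float = 300.0,
                              ) -> tuple[DistanceHistogram, DistanceHistogram]:
    """Metropolis-sample distances from p(r) ~ r^2 exp(-U(r)/kBT) and return
    (observed, reference) histograms, the reference being the r^2-weighted
    uniform distribution on the same bins."""
    rng = np.random.default_rng(seed)
    kt = KB * T
    r = 0.5 * (r_min + r_max)

    def log_p(x: float) -> float:
        if not r_min <= x <= r_max:
            return -math.inf
        return 2.0 * math.log(x) - potential(x) / kt

    lp = log_p(r)
    samples = np.empty(n_samples)
    burn = 2000
    # local Gaussian moves mixed with global uniform proposals: the uniform
    # proposal is independent and symmetric over the interval, so the plain
    # Metropolis ratio applies and the chain decorrelates in a few steps
    for k in range(-burn, n_samples):
        if rng.random() < 0.5:
            prop = r + 0.3 * rng.standard_normal()
        else:
            prop = r_min + (r_max - r_min) * rng.random()
        lp_prop = log_p(prop)
        if math.log(rng.random() + 1e-300) < lp_prop - lp:
            r, lp = prop, lp_prop
        if k >= 0:
            samples[k] = r
    edges = np.linspace(r_min, r_max, n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    obs = DistanceHistogram(type_pair=("A", "B"), bin_edges=edges,
                            counts=counts.astype(float))
    ref = DistanceHistogram(type_pair=("A", "B"), bin_edges=edges,
                            counts=centres ** 2)
    return obs, ref
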