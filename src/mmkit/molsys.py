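"""Molecular data model and file I/O.

The :class:`MolecularSystem` is the container every engine in this package
operates on: a flat list of atoms, a residue segmentation, an undirected bond
graph, and a partition of the atoms into charge groups used by the
neutral-group electrostatics of the crystal module.

Coordinates are Cartesian Angstrom throughout; partial charges are in
elementary-charge units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "MolecularSystem",
    "Topology",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "perceive_topology",
    "COVALENT_RADII",
    "ATOMIC_MASSES",
    "VDW_RADII",
]


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


# Covalent radii (Angstrom), Cordero-style consensus values.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "MG": 1.41, "CA": 1.76, "ZN": 1.22, "FE": 1.32, "SE": 1.20, "B": 0.84,
}

# Atomic masses (amu).
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "SE": 78.971, "B": 10.81,
}

# Bondi-style van der Waals radii (Angstrom) used by the surface-area code.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 2.00, "SE": 1.90, "B": 1.92,
}

_WATER_NAMES = {"HOH", "WAT", "TIP", "SPC", "DOD"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    pos: np.ndarray
    charge: float = 0.0
    ff_type: str = ""
    residue_index: int = 0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    chain: str
    seqnum: int
    icode: str = ""
    atom_indices: list[int] = field(default_factory=list)
    kind: str = "other"  # amino | ligand | water | other
    variant: str = ""    # protonation / flip tag, e.g. "HIE"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)


def classify_residue(name: str) -> str:
    if name in AMINO_ACIDS:
        return "amino"
    if name in _WATER_NAMES:
        return "water"
    return "ligand"


@dataclass
class MolecularSystem:
    atoms: list[Atom] = field(default_factory=list)
    residues: list[Residue] = field(default_factory=list)
    bonds: set[tuple[int, int]] = field(default_factory=set)
    charge_groups: list[list[int]] = field(default_factory=list)
    box: np.ndarray | None = None      # orthorhombic box lengths (3,) or None
    cell: object | None = None         # crystal.UnitCell when read from CRYST1

    # -- construction helpers -------------------------------------------------

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-bond")
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"bond ({i}, {j}) out of range for {n} atoms")
        self.bonds.add((min(i, j), max(i, j)))

    def coords(self) -> np.ndarray:
        """All coordinates as an (N, 3) float64 array (a copy)."""
        return np.array([a.pos for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.pos = p.copy()

    def neighbours(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def default_charge_groups(self) -> None:
        """One charge group per residue (the simplest neutral-group scheme)."""
        self.charge_groups = [list(r.atom_indices) for r in self.residues]

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[int] = set()
        for r in self.residues:
            if not r.atom_indices:
                raise ValueError(f"residue {r.name} {r.seqnum}: empty")
            overlap = seen.intersection(r.atom_indices)
            if overlap:
                raise ValueError(f"atoms {sorted(overlap)} in more than one residue")
            seen.update(r.atom_indices)
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bad bond ({i}, {j})")
        if self.charge_groups:
            flat = sorted(i for g in self.charge_groups for i in g)
            if flat != list(range(n)):
                raise ValueError("charge groups do not partition the atom set")


@dataclass
class Topology:
    """Bonded-term index lists derived from the bond graph.

    ``exclusions`` holds 1-2 and 1-3 pairs (fully excluded from nonbonded
    sums); ``scaled14`` holds pairs at graph distance exactly 3, whose LJ and
    electrostatic interactions are scaled.  The two sets are disjoint.
    """

    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    scaled14: set[tuple[int, int]] = field(default_factory=set)


# -- element inference --------------------------------------------------------

def element_from_name(name: str, element_field: str = "") -> str:
    """Infer the element from PDB columns; atom-name letters as a fallback."""
    el = element_field.strip().upper()
    if el and el in COVALENT_RADII:
        return el
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    # two-letter elements only when the PDB name starts in column 13
    if stripped[:2] in COVALENT_RADII and name[:1].strip() and len(name.strip()) > 1 \
            and stripped[:2] not in ("CA", "CD", "CE", "NA", "ND", "NE", "SE"):
        pass
    if stripped[0] in COVALENT_RADII:
        return stripped[0]
    if stripped[:2] in COVALENT_RADII:
        return stripped[:2]
    raise ParseError(f"unknown element for atom name {name!r}")


# -- PDB ----------------------------------------------------------------------

def read_pdb(text: str) -> MolecularSystem:
    """Parse ATOM/HETATM/TER/CONECT/CRYST1 records into a system.

    Altloc handling keeps the highest-occupancy location (ties: first seen).
    Residues are keyed by (chain, sequence number, insertion code).  CONECT
    records become bonds; remaining covalent structure is perceived from
    distances for HETATM residues and waters.
    """
    records = []          # (serial, name, altloc, resname, chain, seq, icode, xyz, occ, elem, is_het)
    conect: list[tuple[int, int]] = []
    cryst1 = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated {rec.strip()} record")
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed numeric field: {exc}") from None
            occ = 1.0
            if len(line) >= 60 and line[54:60].strip():
                try:
                    occ = float(line[54:60])
                except ValueError:
                    raise ParseError(f"line {lineno}: malformed occupancy") from None
            name = line[12:16].strip()
            altloc = line[16]
            resname = line[17:20].strip()
            chain = line[21].strip()
            try:
                seq = int(line[22:26])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed residue number") from None
            icode = line[26].strip()
            elem = line[76:78] if len(line) >= 78 else ""
            records.append((serial, name, altloc, resname, chain, seq, icode,
                            (x, y, z), occ, elem, rec == "HETATM"))
        elif rec == "CONECT":
            fields = line[6:].split()
            if len(fields) >= 2:
                base = int(fields[0])
                for other in fields[1:]:
                    conect.append((base, int(other)))
        elif rec == "CRYST1":
            try:
                cryst1 = tuple(float(line[6 + 9 * k: 15 + 9 * k]) for k in range(3)) + \
                    tuple(float(line[33 + 7 * k: 40 + 7 * k]) for k in range(3))
            except ValueError:
                raise ParseError(f"line {lineno}: malformed CRYST1 record") from None
    if not records:
        raise ParseError("no ATOM or HETATM records found")

    # altloc resolution: key by (chain, seq, icode, atom name)
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for r in records:
        key = (r[4], r[5], r[6], r[1])
        if key not in best:
            best[key] = r
            order.append(key)
        elif r[8] > best[key][8]:
            best[key] = r

    system = MolecularSystem()
    serial_to_index: dict[int, int] = {}
    res_map: dict[tuple, int] = {}
    for key in order:
        serial, name, _alt, resname, chain, seq, icode, xyz, _occ, elem, is_het = best[key]
        rkey = (chain, seq, icode)
        if rkey not in res_map:
            res_map[rkey] = len(system.residues)
            system.residues.append(Residue(
                name=resname, chain=chain, seqnum=seq, icode=icode,
                kind=classify_residue(resname)))
        ridx = res_map[rkey]
        idx = len(system.atoms)
        system.atoms.append(Atom(
            serial=serial, name=name, element=element_from_name(name, elem),
            pos=np.array(xyz), residue_index=ridx))
        system.residues[ridx].atom_indices.append(idx)
        serial_to_index[serial] = idx

    for a, b in conect:
        if a in serial_to_index and b in serial_to_index and a != b:
            system.add_bond(serial_to_index[a], serial_to_index[b])

    _perceive_missing_bonds(system)
    system.default_charge_groups()

    if cryst1 is not None:
        from .crystal import UnitCell
        a, b, c, al, be, ga = cryst1
        if min(a, b, c) > 0:
            system.cell = UnitCell(a, b, c, al, be, ga)
    system.validate()
    return system


def _perceive_missing_bonds(system: MolecularSystem) -> None:
    """Distance-based bond perception where CONECT/templates left gaps.

    Bonds are added when r < 1.3 x (sum of covalent radii); hydrogens are
    limited to a single bond (their nearest heavy neighbour).  Standard
    amino-acid residues are bonded by template names where possible, by
    distance otherwise.
    """
    from .data import BACKBONE_BONDS, SIDECHAIN_BONDS

    bonded_h = {i for b in system.bonds for i in b if system.atoms[i].element == "H"}

    def try_bond(i: int, j: int) -> None:
        ai, aj = system.atoms[i], system.atoms[j]
        if ai.element == "H" and aj.element == "H":
            return
        if (ai.element == "H" and i in bonded_h) or (aj.element == "H" and j in bonded_h):
            return
        rmax = 1.3 * (COVALENT_RADII.get(ai.element, 0.8) + COVALENT_RADII.get(aj.element, 0.8))
        if float(np.linalg.norm(ai.pos - aj.pos)) < rmax:
            system.add_bond(i, j)
            if ai.element == "H":
                bonded_h.add(i)
            if aj.element == "H":
                bonded_h.add(j)

    # intra-residue
    for res in system.residues:
        idx = res.atom_indices
        if res.kind == "amino":
            byname = {system.atoms[i].name: i for i in idx}
            pairs = BACKBONE_BONDS + SIDECHAIN_BONDS.get(res.name, [])
            for a, b in pairs:
                if a in byname and b in byname:
                    key = (min(byname[a], byname[b]), max(byname[a], byname[b]))
                    if key not in system.bonds:
                        try_bond(*key)
            # hydrogens and any unnamed atoms by distance
            for i in idx:
                for j in idx:
                    if i < j and (i, j) not in system.bonds:
                        if system.atoms[i].element == "H" or system.atoms[j].element == "H":
                            try_bond(i, j)
        else:
            for i, j in combinations(idx, 2):
                if (i, j) not in system.bonds and (j, i) not in system.bonds:
                    try_bond(min(i, j), max(i, j))
    # peptide bonds between consecutive amino residues on the same chain
    for r1, r2 in zip(system.residues, system.residues[1:]):
        if r1.kind == r2.kind == "amino" and r1.chain == r2.chain:
            c = next((i for i in r1.atom_indices if system.atoms[i].name == "C"), None)
            n = next((i for i in r2.atom_indices if system.atoms[i].name == "N"), None)
            if c is not None and n is not None:
                try_bond(min(c, n), max(c, n))


def write_pdb(system: MolecularSystem) -> str:
    """Serialise to fixed-column PDB text (ATOM/HETATM/TER/CONECT, CRYST1)."""
    if not system.atoms:
        raise ValueError("cannot write an empty system")
    lines: list[str] = []
    if system.cell is not None:
        c = system.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1")
    # canonical output order: residue-grouped, sequentially renumbered
    serial_of: dict[int, int] = {}
    for res in system.residues:
        for i in res.atom_indices:
            serial_of[i] = len(serial_of) + 1
    for ridx, res in enumerate(system.residues):
        rec = "ATOM  " if res.kind == "amino" else "HETATM"
        for i in res.atom_indices:
            a = system.atoms[i]
            if np.max(np.abs(a.pos)) >= 10000.0:
                raise ValueError(f"atom {a.serial}: coordinate magnitude >= 10000 A")
            name = a.name if len(a.name) >= 4 or len(a.element) == 2 else f" {a.name}"
            lines.append(
                f"{rec}{serial_of[i]:5d} {name:<4.4s} {res.name:<3.3s} {res.chain or 'A':1.1s}"
                f"{res.seqnum:4d}{res.icode or ' ':1.1s}   "
                f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}")
        if ridx + 1 < len(system.residues) and system.residues[ridx + 1].chain != res.chain:
            lines.append("TER")
    adj = system.neighbours()
    for i in sorted(serial_of, key=serial_of.get):
        if adj[i]:
            nb = sorted(serial_of[j] for j in adj[i])
            for chunk in range(0, len(nb), 4):
                part = nb[chunk:chunk + 4]
                lines.append("CONECT" + f"{serial_of[i]:5d}" + "".join(f"{j:5d}" for j in part))
    lines.append("END")
    return "\n".join(lines) + "\n"


# -- XYZ ----------------------------------------------------------------------

def read_xyz(text: str) -> MolecularSystem:
    """Parse standard XYZ text (count line, comment, element x y z rows)."""
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ParseError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise ParseError("line 1: expected an atom count") from None
    body = lines[2:2 + n]
    if len(body) < n:
        raise ParseError(f"atom count {n} exceeds the {len(body)} coordinate lines present")
    system = MolecularSystem()
    system.residues.append(Residue(name="MOL", chain="A", seqnum=1, kind="ligand"))
    for k, line in enumerate(body):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"line {k + 3}: expected 'element x y z'")
        el = fields[0].upper()
        if el not in COVALENT_RADII:
            el = element_from_name(fields[0])
        try:
            xyz = [float(v) for v in fields[1:4]]
        except ValueError:
            raise ParseError(f"line {k + 3}: malformed coordinate") from None
        system.atoms.append(Atom(serial=k + 1, name=fields[0], element=el,
                                 pos=np.array(xyz), residue_index=0))
        system.residues[0].atom_indices.append(k)
    _perceive_missing_bonds(system)
    system.default_charge_groups()
    return system


def write_xyz(system: MolecularSystem, comment: str = "") -> str:
    if not system.atoms:
        raise ValueError("cannot write an empty system")
    lines = [str(len(system.atoms)), comment.replace("\n", " ")]
    for a in system.atoms:
        lines.append(f"{a.element.capitalize():<2s} {a.pos[0]:14.6f} {a.pos[1]:14.6f} {a.pos[2]:14.6f}")
    return "\n".join(lines) + "\n"


# -- topology perception ------------------------------------------------------

def perceive_topology(system: MolecularSystem) -> Topology:
    """Enumerate angles, torsions and nonbonded exclusion sets from the bonds.

    Angles are all bonded paths i-j-k; proper torsions all simple paths
    i-j-k-l.  Pairs at graph distance 1 or 2 are excluded from nonbonded
    sums, pairs at distance exactly 3 go into the scaled 1-4 set.  Impropers
    are generated for every atom with exactly three bonded neighbours (they
    only contribute energy if the parameter set defines them).
    """
    adj = system.neighbours()
    top = Topology(bonds=sorted(system.bonds))
    for j, nb in enumerate(adj):
        for i, k in combinations(sorted(nb), 2):
            top.angles.append((i, j, k))
    for j, k in top.bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                top.torsions.append(quad if i < l else (l, k, j, i))
    top.torsions = sorted(set(top.torsions))
    for c, nb in enumerate(adj):
        if len(nb) == 3:
            a, b, d = sorted(nb)
            top.impropers.append((a, b, c, d))

    dist = _graph_distances_upto(adj, 3)
    for (i, j), d in dist.items():
        if d <= 2:
            top.exclusions.add((i, j))
        elif d == 3:
            top.scaled14.add((i, j))
    return top


def _graph_distances_upto(adj: list[list[int]], cutoff: int) -> dict[tuple[int, int], int]:
    """BFS graph distances for all pairs with distance <= cutoff."""
    out: dict[tuple[int, int], int] = {}
    for src in range(len(adj)):
        frontier = [src]
        dist = {src: 0}
        for d in range(1, cutoff + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if src < v:
                out[(src, v)] = d
    return out


def measure_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float)))


def measure_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))
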