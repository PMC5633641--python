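"""Structure preparation and search tools: rotamer enumeration and scanning,
riding-hydrogen placement, polar-hydrogen optimisation (hydroxyl torsions,
His/Gln/Asn flips, His tautomers), and solvent-accessible / polar surface
areas.

Rotamer conventions: side-chain torsions chi1..chi4; the built-in three-state
library is the Cartesian product of gauche- (-60), gauche+ (+60) and trans
(180) over the rotatable chi bonds of each residue, which spans 1 rotamer
(Gly, Ala) to 81 (Lys).  External Richardson/Dunbrack-style libraries load
from a simple text format (residue name followed by chi values, one rotamer
per line).
"""

from __future__ import annotations

import copy
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .data import (CHI_ATOMS, CHI_COUNTS, FLIPPABLE, HYDROGEN_COUNTS,
                   ROTATABLE_HYDROXYLS, XH_BOND_LENGTHS)
from .data.residues import HIS_VARIANTS
from .forcefield import NonbondedSettings, ParameterSet, energy_and_gradient
from .internal_coords import measure_dihedral, place_by_internal, set_torsion
from .molsys import (VDW_RADII, Atom, MolecularSystem, Topology,
                     perceive_topology)
from .scoring import PairPotentialTable, score_pose, type_by_element

__all__ = [
    "RotamerLibrary", "RotamerScanOptions", "ScanResult", "FlipDecision",
    "enumerate_rotamers", "apply_rotamer", "rotamer_scan",
    "place_missing_hydrogens", "optimize_polar_hydrogens",
    "sasa", "polar_surface_area", "sphere_points",
]

THREE_STATES = (-60.0, 60.0, 180.0)   # gauche-, gauche+, trans


# -- rotamer library ----------------------------------------------------------

@dataclass
class RotamerLibrary:
    entries: dict[str, list[tuple[float, ...]]] = field(default_factory=dict)
    source: str = "three_state"

    @classmethod
    def three_state(cls) -> "RotamerLibrary":
        entries = {}
        for name, nchi in CHI_COUNTS.items():
            entries[name] = [tuple(t) for t in itertools.product(THREE_STATES, repeat=nchi)]
        return cls(entries=entries, source="three_state")

    @classmethod
    def from_text(cls, text: str) -> "RotamerLibrary":
        """Parse 'RES chi1 [chi2 ...]' lines (degrees, # comments allowed)."""
        entries: dict[str, list[tuple[float, ...]]] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            f = line.split()
            name = f[0].upper()
            try:
                chi = tuple(float(v) for v in f[1:])
            except ValueError:
                raise ValueError(f"rotamer file line {lineno}: malformed chi value") from None
            expected = CHI_COUNTS.get(name)
            if expected is not None and len(chi) != expected:
                raise ValueError(f"rotamer file line {lineno}: {name} takes "
                                 f"{expected} chi angles, got {len(chi)}")
            entries.setdefault(name, []).append(chi)
        return cls(entries=entries, source="file")

    def rotamers(self, residue_name: str) -> list[tuple[float, ...]]:
        if residue_name not in self.entries:
            raise KeyError(f"no rotamers for residue {residue_name!r}")
        return self.entries[residue_name]


def enumerate_rotamers(residue_name: str,
                       library: RotamerLibrary | None = None) -> list[tuple[float, ...]]:
    """All rotamers of a residue: 3^n_chi tuples in three-state mode."""
    if library is None:
        library = RotamerLibrary.three_state()
    return library.rotamers(residue_name)


def _atom_index(system: MolecularSystem, ridx: int, name: str) -> int:
    for i in system.residues[ridx].atom_indices:
        if system.atoms[i].name == name:
            return i
    raise KeyError(f"residue {system.residues[ridx].name} {ridx}: no atom {name!r}")


def apply_rotamer(system: MolecularSystem, ridx: int,
                  chi: tuple[float, ...]) -> MolecularSystem:
    """Set the side-chain torsions of a residue to ``chi`` (chi1 first).
    Backbone atoms do not move."""
    name = system.residues[ridx].name
    quads = CHI_ATOMS.get(name)
    if quads is None:
        raise KeyError(f"unknown residue {name!r}")
    if len(chi) != len(quads):
        raise ValueError(f"{name} takes {len(quads)} chi angles, got {len(chi)}")
    for value, quad_names in zip(chi, quads):
        quad = tuple(_atom_index(system, ridx, nm) for nm in quad_names)
        set_torsion(system, quad, value)
    return system


# -- rotamer scanning ---------------------------------------------------------

@dataclass
class RotamerScanOptions:
    residues: list[int] = field(default_factory=list)
    top_k: int = 10
    scorer: str = "dfire"          # dfire | forcefield
    rescore: bool = False
    max_combinations: int = 1_000_000

    def __post_init__(self):
        if not 1 <= len(self.residues) <= 6:
            raise ValueError("rotamer scans handle between 1 and 6 residues")


@dataclass
class ScanResult:
    # (chi assignment per residue, score, rescore-or-None), ascending score
    ranked: list[tuple[tuple[tuple[float, ...], ...], float, float | None]]


def rotamer_scan(system: MolecularSystem, options: RotamerScanOptions,
                 library: RotamerLibrary | None = None,
                 tables: dict[tuple[str, str], PairPotentialTable] | None = None,
                 topology: Topology | None = None,
                 params: ParameterSet | None = None,
                 settings: NonbondedSettings | None = None) -> ScanResult:
    """Exhaustive scan over the rotamer product space of the selected
    residues.

    Every combination is applied and scored against the rest of the
    structure (statistical pair potential by default, force field on
    request); the best ``top_k`` are kept (stable ascending sort, ties in
    enumeration order).  With ``rescore=True`` each kept combination gains a
    force-field energy without reordering the primary ranking.
    """
    if library is None:
        library = RotamerLibrary.three_state()
    work = copy.deepcopy(system)
    per_res = [library.rotamers(work.residues[r].name) for r in options.residues]
    n_comb = math.prod(len(r) for r in per_res)
    if n_comb > options.max_combinations:
        raise ValueError(f"scan would enumerate {n_comb} combinations "
                         f"(limit {options.max_combinations})")
    scan_atoms: list[int] = []
    for r in options.residues:
        scan_atoms.extend(work.residues[r].atom_indices)
    env_atoms = [i for i in range(len(work.atoms)) if i not in set(scan_atoms)]
    if options.scorer == "forcefield" or options.rescore:
        if topology is None:
            topology = perceive_topology(work)
        if params is None:
            raise ValueError("force-field scoring needs a parameter set")
    if options.scorer == "dfire" and tables is None:
        raise ValueError("statistical scoring needs pair-potential tables")

    def stat_score() -> float:
        xyz = work.coords()
        types = type_by_element(work)
        s = score_pose(xyz[env_atoms], [types[i] for i in env_atoms],
                       xyz[scan_atoms], [types[i] for i in scan_atoms], tables).total
        # pairs between distinct scan residues
        for a, b in itertools.combinations(options.residues, 2):
            ia = work.residues[a].atom_indices
            ib = work.residues[b].atom_indices
            s += score_pose(xyz[ia], [types[i] for i in ia],
                            xyz[ib], [types[i] for i in ib], tables).total
        return s

    def ff_score() -> float:
        rep, _ = energy_and_gradient(work, topology, params, settings)
        return rep.total

    primary = stat_score if options.scorer == "dfire" else ff_score
    kept: list[tuple[tuple, float, float | None]] = []
    for combo in itertools.product(*per_res):
        for ridx, chi in zip(options.residues, combo):
            apply_rotamer(work, ridx, chi)
        kept.append((combo, primary(), None))
    kept.sort(key=lambda t: t[1])   # stable: enumeration order breaks ties
    kept = kept[:options.top_k]
    if options.rescore:
        rescored = []
        for combo, score, _ in kept:
            for ridx, chi in zip(options.residues, combo):
                apply_rotamer(work, ridx, chi)
            rescored.append((combo, score, ff_score()))
        kept = rescored
    return ScanResult(ranked=kept)


# -- hydrogen placement -------------------------------------------------------

_TETRA = 109.471


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _h_targets_amino(res_name: str, variant: str) -> dict[str, tuple[int, str]]:
    targets = dict(HYDROGEN_COUNTS.get(res_name, {}))
    if res_name == "HIS":
        targets.update(HIS_VARIANTS.get(variant or "HIE", HIS_VARIANTS["HIE"]))
        targets = {k: v for k, v in targets.items() if v[0] > 0 or k not in ("ND1", "NE2")}
    targets.setdefault("CA", (2, "sp3") if res_name == "GLY" else (1, "sp3"))
    if res_name != "PRO":
        targets.setdefault("N", (1, "sp2"))
    return targets


def _h_name(parent: str, k: int, n_h: int) -> str:
    if parent == "N":
        return "H" if n_h == 1 else f"H{k + 1}"
    suffix = parent[1:] if len(parent) > 1 else parent
    if parent == "CA" and n_h == 1:
        return "HA"
    return f"H{suffix}" if n_h == 1 else f"H{suffix}{k + 1}"


def place_missing_hydrogens(system: MolecularSystem,
                            residues: list[int] | None = None,
                            report: list[str] | None = None) -> MolecularSystem:
    """Add riding protons from ideal sp3/sp2 geometry.

    Amino residues use the per-atom hydrogen-count templates (His follows the
    residue's tautomer ``variant``, default epsilon-protonated); other
    residues use a valence heuristic (carbonyl oxygens and planar ring
    carbons treated as sp2).  Heavy atoms whose environment cannot be
    templated are skipped and noted in ``report``.
    """
    if residues is None:
        residues = list(range(len(system.residues)))
    for ridx in residues:
        res = system.residues[ridx]
        adj = system.neighbours()
        existing_h = {i: sum(1 for j in adj[i] if system.atoms[j].element == "H")
                      for i in res.atom_indices}
        if res.kind == "amino":
            targets = _h_targets_amino(res.name, res.variant)
            byname = {system.atoms[i].name: i for i in res.atom_indices}
            # chain-terminal tweaks: free amine N gets 2 H, C-terminal OXT 1 H
            if "N" in byname and not any(system.atoms[j].name == "C" for j in adj[byname["N"]]):
                if res.name != "PRO":
                    targets["N"] = (2, "sp3")
            if "OXT" in byname:
                targets["OXT"] = (1, "sp3")
            for name, (n_h, hyb) in targets.items():
                if name not in byname:
                    if report is not None:
                        report.append(f"residue {res.name} {res.seqnum}: missing heavy atom {name}")
                    continue
                i = byname[name]
                missing = n_h - existing_h.get(i, 0)
                if missing > 0:
                    _attach_hydrogens(system, i, missing, hyb,
                                      lambda k: _h_name(name, k + existing_h.get(i, 0), n_h))
        else:
            for i in list(res.atom_indices):
                spec = _heuristic_h(system, i, adj)
                if spec is None:
                    if report is not None:
                        a = system.atoms[i]
                        report.append(f"atom {a.name} ({a.element}) in {res.name}: "
                                      "environment not templated, skipped")
                    continue
                n_h, hyb = spec
                missing = n_h - existing_h.get(i, 0)
                if missing > 0:
                    el = system.atoms[i].element
                    _attach_hydrogens(system, i, missing, hyb,
                                      lambda k, el=el, i=i: f"H{system.atoms[i].name[1:] or ''}{k + 1}")
    system.default_charge_groups()
    return system


def _heuristic_h(system: MolecularSystem, i: int, adj) -> tuple[int, str] | None:
    """Valence-based hydrogen count for non-amino atoms."""
    a = system.atoms[i]
    heavy = [j for j in adj[i] if system.atoms[j].element != "H"]
    deg = len(heavy)
    if a.element == "C":
        if _in_planar_ring(system, i, adj):
            return max(3 - deg, 0), "sp2"
        if any(system.atoms[j].element == "O" and len(adj[j]) == 1 and
               np.linalg.norm(system.atoms[j].pos - a.pos) < 1.28 for j in heavy):
            return max(3 - deg, 0), "sp2"
        return max(4 - deg, 0), "sp3"
    if a.element == "N":
        if _in_planar_ring(system, i, adj):
            return None  # pyridine vs pyrrole is ambiguous without bond orders
        return max(3 - deg, 0), "sp3"
    if a.element == "O":
        if deg == 0:
            return 2, "sp3"   # water
        if deg == 1:
            near_c = system.atoms[heavy[0]].element == "C" and \
                np.linalg.norm(system.atoms[heavy[0]].pos - a.pos) < 1.28
            return (0, "sp2") if near_c else (1, "sp3")
        return 0, "sp3"
    if a.element == "S":
        return (1, "sp3") if deg <= 1 else (0, "sp3")
    return None


def _in_planar_ring(system: MolecularSystem, i: int, adj) -> bool:
    """Is atom i part of a 5/6-membered ring that is planar to ~0.15 A?"""
    ring = _find_ring(adj, i)
    if ring is None:
        return False
    pts = np.array([system.atoms[j].pos for j in ring])
    centred = pts - pts.mean(axis=0)
    _, s, _ = np.linalg.svd(centred)
    return s[-1] < 0.15 * math.sqrt(len(ring))


def _find_ring(adj, start: int, max_size: int = 6):
    """Smallest cycle (size 5 or 6) through ``start``, or None."""
    for size in (5, 6):
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            for nxt in adj[node]:
                if nxt == start and len(path) == size:
                    return path
                if nxt not in path and len(path) < size:
                    stack.append((nxt, path + [nxt]))
    return None


def _attach_hydrogens(system: MolecularSystem, i: int, n_new: int, hyb: str,
                      namer) -> None:
    a = system.atoms[i]
    r = XH_BOND_LENGTHS.get(a.element, 1.09)
    adj = system.neighbours()
    nb = adj[i]
    X = a.pos
    positions: list[np.ndarray] = []
    if len(nb) == 0:
        dirs = {1: [np.array([1.0, 0, 0])],
                2: [np.array([1.0, 0, 0]),
                    np.array([math.cos(math.radians(104.5)), math.sin(math.radians(104.5)), 0])],
                3: [np.array([1.0, 0, 0]),
                    np.array([math.cos(math.radians(_TETRA)), math.sin(math.radians(_TETRA)), 0]),
                    _rotated_tetra(2)],
                4: [np.array(v) / math.sqrt(3) for v in
                    ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]}[min(n_new, 4)]
        positions = [X + r * d for d in dirs[:n_new]]
    elif len(nb) == 1:
        b = nb[0]
        pb = system.atoms[b].pos
        second = next((j for j in adj[b] if j != i), None)
        if second is None:
            ref = pb + _any_perpendicular(X - pb)
        else:
            ref = system.atoms[second].pos
        angle = _TETRA if hyb == "sp3" else 120.0
        taus = {1: [180.0], 2: ([0.0, 180.0] if hyb == "sp2" else [60.0, -60.0]),
                3: [180.0, 60.0, -60.0]}[min(n_new, 3)]
        positions = [place_by_internal(ref, pb, X, r, angle, t) for t in taus[:n_new]]
    elif len(nb) == 2:
        d1 = _unit(X - system.atoms[nb[0]].pos)
        d2 = _unit(X - system.atoms[nb[1]].pos)
        bis = _unit(d1 + d2)
        if hyb == "sp2" or n_new == 1:
            positions = [X + r * bis]
        else:
            perp = _unit(np.cross(d1, d2))
            half = math.radians(_TETRA / 2.0)
            positions = [X + r * (bis * math.cos(half) + s * perp * math.sin(half))
                         for s in (1.0, -1.0)][:n_new]
    else:
        dsum = np.sum([_unit(system.atoms[j].pos - X) for j in nb], axis=0)
        positions = [X + r * _unit(-dsum)]
    serial = max(at.serial for at in system.atoms) + 1
    ridx = a.residue_index
    for k, pos in enumerate(positions[:n_new]):
        idx = len(system.atoms)
        system.atoms.append(Atom(serial=serial + k, name=namer(k), element="H",
                                 pos=pos, residue_index=ridx))
        system.residues[ridx].atom_indices.append(idx)
        system.add_bond(i, idx)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate direction")
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    v = _unit(v)
    other = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, other))


def _rotated_tetra(k: int) -> np.ndarray:
    th = math.radians(_TETRA)
    return np.array([math.cos(th), math.sin(th) * math.cos(2 * math.pi * k / 3),
                     math.sin(th) * math.sin(2 * math.pi * k / 3)])


# -- polar hydrogen optimisation ----------------------------------------------

@dataclass
class FlipDecision:
    residue: int
    states: list[str]
    energies: list[float]
    chosen: str
    degenerate: bool = False


def optimize_polar_hydrogens(system: MolecularSystem, topology: Topology,
                             params: ParameterSet,
                             settings: NonbondedSettings | None = None,
                             grid_step: float = 10.0,
                             max_sweeps: int = 10,
                             ) -> tuple[MolecularSystem, list[FlipDecision]]:
    """Optimise rotatable polar hydrogens and side-chain flips by direct
    force-field energy comparison.

    Ser/Thr/Tyr hydroxyl torsions are grid-searched in ``grid_step`` degree
    steps; Asn/Gln/His terminal groups are evaluated unflipped vs flipped
    (180-degree rotation of the terminal torsion); sites are revisited until
    no change, at most ``max_sweeps`` sweeps.  Degenerate sites (energy
    spread below 1e-6) keep their input state and are flagged.
    """
    decisions: list[FlipDecision] = []

    def energy() -> float:
        rep, _ = energy_and_gradient(system, topology, params, settings)
        return rep.total

    # collect sites once
    hydroxyls = []   # (ridx, torsion quad)
    flips = []       # (ridx, torsion quad)
    adj = system.neighbours()
    for ridx, res in enumerate(system.residues):
        if res.kind != "amino":
            continue
        byname = {system.atoms[i].name: i for i in res.atom_indices}
        if res.name in ROTATABLE_HYDROXYLS:
            o_name, parent = ROTATABLE_HYDROXYLS[res.name]
            if o_name in byname:
                o = byname[o_name]
                h = next((j for j in adj[o] if system.atoms[j].element == "H"), None)
                gp = next((j for j in adj[byname[parent]]
                           if j != o and system.atoms[j].element != "H"), None)
                if h is not None and gp is not None:
                    hydroxyls.append((ridx, (gp, byname[parent], o, h)))
        if res.name in FLIPPABLE:
            quad_names = FLIPPABLE[res.name]
            if all(nm in byname for nm in quad_names):
                flips.append((ridx, tuple(byname[nm] for nm in quad_names)))

    changed = True
    sweep = 0
    flip_state: dict[int, str] = {r: "input" for r, _ in flips}
    while changed and sweep < max_sweeps:
        changed = False
        sweep += 1
        for ridx, quad in hydroxyls:
            current = measure_dihedral(*(system.atoms[i].pos for i in quad))
            best_t, best_e = current, energy()
            e0 = best_e
            energies = [best_e]
            for t in np.arange(-180.0, 180.0, grid_step):
                set_torsion(system, quad, float(t))
                e = energy()
                energies.append(e)
                if e < best_e - 1e-9:
                    best_t, best_e = float(t), e
            degenerate = (max(energies) - min(energies)) < 1e-6
            set_torsion(system, quad, current if degenerate else best_t)
            if not degenerate and abs(best_t - current) > 1e-6 and best_e < e0 - 1e-9:
                changed = True
            if sweep == 1:
                decisions.append(FlipDecision(residue=ridx, states=["hydroxyl-grid"],
                                              energies=[e0, best_e],
                                              chosen=f"{best_t:.1f}",
                                              degenerate=degenerate))
        for ridx, quad in flips:
            current = measure_dihedral(*(system.atoms[i].pos for i in quad))
            e_in = energy()
            set_torsion(system, quad, current + 180.0)
            e_flip = energy()
            if e_flip < e_in - 1e-6:
                if flip_state[ridx] != "flipped":
                    flip_state[ridx] = "flipped"
                    changed = True
                chosen, deg = "flipped", False
            else:
                set_torsion(system, quad, current)
                chosen = flip_state[ridx]
                deg = abs(e_flip - e_in) <= 1e-6
            if sweep == 1:
                decisions.append(FlipDecision(residue=ridx,
                                              states=["input", "flipped"],
                                              energies=[e_in, e_flip],
                                              chosen=chosen, degenerate=deg))
    return system, decisions


# -- surface areas ------------------------------------------------------------

def sasa(system: MolecularSystem, probe: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) by sphere sampling.

    Each atom's accessible sphere (vdW radius + probe) is sampled with a
    deterministic golden-spiral point set; points buried inside any other
    atom's accessible sphere are discarded.
    """
    n = len(system.atoms)
    radii = np.array([VDW_RADII.get(a.element, 1.7) + probe for a in system.atoms])
    xyz = system.coords()
    pts = sphere_points(n_points)
    areas = np.zeros(n)
    for i in range(n):
        shell = xyz[i] + radii[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(xyz[j] - xyz[i]) >= radii[i] + radii[j]:
                continue
            d2 = np.sum((shell - xyz[j]) ** 2, axis=1)
            free &= d2 > radii[j] ** 2
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * free.mean()
    return areas


def polar_surface_area(system: MolecularSystem, probe: float = 1.4,
                       n_points: int = 960) -> float:
    """Polar surface area: summed accessible area of N and O atoms plus
    hydrogens bonded to N or O."""
    areas = sasa(system, probe=probe, n_points=n_points)
    adj = system.neighbours()
    total = 0.0
    for i, a in enumerate(system.atoms):
        if a.element in ("N", "O"):
            total += areas[i]
        elif a.element == "H" and any(system.atoms[j].element in ("N", "O")
                                      for j in adj[i]):
            total += areas[i]
    return float(total)
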