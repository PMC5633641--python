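"""Internal coordinates: Z-matrix construction and conversion, torsion
measurement and editing, residue mutation, Ramachandran classification.

A Z-matrix defines each atom by a bond length, bond angle and dihedral angle
relative to previously defined atoms.  Conversion to Cartesian space uses the
natural-extension reference frame (NeRF) placement; the first three atoms fix
the global frame (origin, +x axis, +y half of the xy plane).

Angles are degrees at every public interface; dihedrals follow the IUPAC sign
convention (cis = 0, values in (-180, 180]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import CHI_ATOMS, HYDROGEN_COUNTS, RAMA_ALLOWED, RAMA_FAVOURED, SIDECHAIN_TEMPLATES
from .molsys import Atom, MolecularSystem

__all__ = [
    "ZMatrixRow", "ZMatrix", "DegenerateGeometryError", "RingTorsionError",
    "measure_dihedral", "zmatrix_to_cartesian", "cartesian_to_zmatrix",
    "read_zmatrix_text", "write_zmatrix_text", "set_torsion",
    "backbone_torsions", "mutate_residue", "classify_ramachandran",
    "place_by_internal",
]


class DegenerateGeometryError(ValueError):
    """A bond angle of 0 or 180 degrees makes a dependent dihedral undefined."""


class RingTorsionError(ValueError):
    """The central bond of the requested torsion lies in a ring."""


@dataclass
class ZMatrixRow:
    element: str
    bond_ref: int | None = None      # index into previous rows
    angle_ref: int | None = None
    dihedral_ref: int | None = None
    bond: float = 0.0                # Angstrom
    angle: float = 0.0               # degrees
    dihedral: float = 0.0            # degrees


@dataclass
class ZMatrix:
    rows: list[ZMatrixRow] = field(default_factory=list)

    def validate(self) -> None:
        for k, row in enumerate(self.rows):
            refs = [row.bond_ref, row.angle_ref, row.dihedral_ref]
            needed = min(k, 3)
            for r in refs[:needed]:
                if r is None or not (0 <= r < k):
                    raise ValueError(f"row {k}: reference {r} not previously defined")
            if len({r for r in refs[:needed]}) != needed:
                raise ValueError(f"row {k}: duplicate references")


# -- geometry primitives ------------------------------------------------------

def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, cis = 0, in (-180, 180].

    Undefined (raises) when p1 or p4 is collinear with the central p2-p3 axis.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = _unit(p3 - p2, "central bond")
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise DegenerateGeometryError("dihedral undefined: terminal atom collinear with axis")
    ang = math.degrees(math.atan2(float(np.dot(np.cross(b1, v), w)), float(np.dot(v, w))))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_by_internal(pd: np.ndarray, pa: np.ndarray, pb: np.ndarray,
                      r: float, theta_deg: float, tau_deg: float) -> np.ndarray:
    """Place a new atom at distance ``r`` from ``pb``, angle ``theta`` at
    ``pb`` towards ``pa``, and dihedral ``tau`` about the ``pa``-``pb`` axis
    relative to ``pd`` (NeRF placement): dihedral(pd, pa, pb, new) = tau."""
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = _unit(pb - pa, "angle-reference bond")
    n = np.cross(pa - pd, bc)
    if np.linalg.norm(n) < 1e-10:
        raise DegenerateGeometryError("dihedral reference collinear with angle reference")
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(theta), r * math.sin(theta) * math.cos(tau),
                  r * math.sin(theta) * math.sin(tau)])
    return pb + d[0] * bc + d[1] * m + d[2] * n


def zmatrix_to_cartesian(z: ZMatrix) -> np.ndarray:
    """Convert a Z-matrix to an (N, 3) coordinate array.

    Convention: atom 0 at the origin, atom 1 on +x, atom 2 in the xy plane
    with positive y.
    """
    z.validate()
    n = len(z.rows)
    xyz = np.zeros((n, 3))
    for k, row in enumerate(z.rows):
        if k == 0:
            continue
        if k == 1:
            xyz[1] = xyz[row.bond_ref] + np.array([row.bond, 0.0, 0.0])
            continue
        if not (1e-9 < row.angle < 180.0 - 1e-9) and k >= 3:
            raise DegenerateGeometryError(
                f"row {k}: angle {row.angle} deg makes the dihedral undefined")
        if k == 2:
            pb = xyz[row.bond_ref]
            pa = xyz[row.angle_ref]
            u = _unit(pa - pb)
            th = math.radians(row.angle)
            # rotate u by theta within the xy plane, +y side
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-12:
                perp = np.array([0.0, 1.0, 0.0])
            else:
                perp = perp / np.linalg.norm(perp)
            cand = pb + row.bond * (math.cos(th) * u + math.sin(th) * perp)
            if cand[1] < 0:
                cand = pb + row.bond * (math.cos(th) * u - math.sin(th) * perp)
            xyz[2] = cand
            continue
        xyz[k] = place_by_internal(
            xyz[row.dihedral_ref], xyz[row.angle_ref], xyz[row.bond_ref],
            row.bond, row.angle, row.dihedral)
    return xyz


def cartesian_to_zmatrix(system: MolecularSystem, order: list[int] | None = None) -> ZMatrix:
    """Build a Z-matrix from Cartesian coordinates.

    References for each row are chosen as the nearest previously defined
    atoms that give a non-degenerate angle and dihedral (bonded atoms
    preferred for the bond reference).
    """
    if not system.atoms:
        raise ValueError("cannot build a Z-matrix from an empty system")
    if order is None:
        order = list(range(len(system.atoms)))
    pos = [system.atoms[i].pos for i in order]
    adj = system.neighbours()
    z = ZMatrix()
    placed: dict[int, int] = {}
    for k, iorig in enumerate(order):
        row = ZMatrixRow(element=system.atoms[iorig].element)
        if k >= 1:
            prev = list(range(k))
            bonded = [placed[j] for j in adj[iorig] if j in placed]
            pool = bonded if bonded else prev
            b = min(pool, key=lambda j: np.linalg.norm(pos[k] - pos[j]))
            row.bond_ref = b
            row.bond = float(np.linalg.norm(pos[k] - pos[b]))
        if k >= 2:
            a = _pick_angle_ref(pos, k, row.bond_ref)
            row.angle_ref = a
            row.angle = _angle_deg(pos[k], pos[row.bond_ref], pos[a])
        if k >= 3:
            d = _pick_dihedral_ref(pos, k, row.bond_ref, row.angle_ref)
            row.dihedral_ref = d
            row.dihedral = measure_dihedral(pos[d], pos[row.angle_ref],
                                            pos[row.bond_ref], pos[k])
        z.rows.append(row)
        placed[iorig] = k
    return z


def _angle_deg(p, q, r) -> float:
    v1 = _unit(np.asarray(p, float) - np.asarray(q, float))
    v2 = _unit(np.asarray(r, float) - np.asarray(q, float))
    return math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(v1, v2))))))


def _pick_angle_ref(pos, k, bond_ref) -> int:
    cands = sorted((j for j in range(k) if j != bond_ref),
                   key=lambda j: np.linalg.norm(pos[k] - pos[j]))
    for j in cands:
        ang = _angle_deg(pos[k], pos[bond_ref], pos[j])
        if 1e-3 < ang < 180.0 - 1e-3:
            return j
    raise DegenerateGeometryError(f"row {k}: all candidate angle references collinear")


def _pick_dihedral_ref(pos, k, bond_ref, angle_ref) -> int:
    cands = sorted((j for j in range(k) if j not in (bond_ref, angle_ref)),
                   key=lambda j: np.linalg.norm(pos[k] - pos[j]))
    for j in cands:
        axis = pos[bond_ref] - pos[angle_ref]
        v = pos[j] - pos[angle_ref]
        if np.linalg.norm(np.cross(axis, v)) > 1e-6 * max(np.linalg.norm(axis), 1.0):
            return j
    raise DegenerateGeometryError(f"row {k}: all candidate dihedral references collinear")


# -- Z-matrix text format -----------------------------------------------------

def write_zmatrix_text(z: ZMatrix) -> str:
    """One row per line: element [ref1 bond [ref2 angle [ref3 dihedral]]],
    with 1-based references."""
    lines = []
    for k, row in enumerate(z.rows):
        parts = [f"{row.element:<2s}"]
        if k >= 1:
            parts += [str(row.bond_ref + 1), f"{row.bond:.6f}"]
        if k >= 2:
            parts += [str(row.angle_ref + 1), f"{row.angle:.6f}"]
        if k >= 3:
            parts += [str(row.dihedral_ref + 1), f"{row.dihedral:.6f}"]
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


def read_zmatrix_text(text: str) -> ZMatrix:
    z = ZMatrix()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        f = line.split()
        k = len(z.rows)
        try:
            row = ZMatrixRow(element=f[0].upper())
            if k >= 1:
                row.bond_ref, row.bond = int(f[1]) - 1, float(f[2])
            if k >= 2:
                row.angle_ref, row.angle = int(f[3]) - 1, float(f[4])
            if k >= 3:
                row.dihedral_ref, row.dihedral = int(f[5]) - 1, float(f[6])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"Z-matrix line {lineno}: {exc}") from None
        z.rows.append(row)
    z.validate()
    return z


# -- torsion editing ----------------------------------------------------------

def _split_by_bond(system: MolecularSystem, j: int, k: int) -> tuple[set[int], set[int]]:
    """Partition atoms by removing bond j-k; raises RingTorsionError if j and
    k stay connected."""
    adj = system.neighbours()
    seen = {k}
    stack = [k]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if (u, v) in ((j, k), (k, j)):
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if j in seen:
        raise RingTorsionError(f"bond {j}-{k} lies in a ring; torsion not rotatable")
    side_k = seen
    side_j = set(range(len(system.atoms))) - side_k
    return side_j, side_k


def set_torsion(system: MolecularSystem, quad: tuple[int, int, int, int],
                value: float) -> MolecularSystem:
    """Rotate about the central bond of ``quad`` so the measured dihedral
    equals ``value`` (degrees).  Only the smaller of the two components
    separated by the bond moves (ties: the far side moves)."""
    i, j, k, l = quad
    side_j, side_k = _split_by_bond(system, j, k)
    current = measure_dihedral(system.atoms[i].pos, system.atoms[j].pos,
                               system.atoms[k].pos, system.atoms[l].pos)
    delta = math.radians(value - current)
    axis = _unit(system.atoms[k].pos - system.atoms[j].pos, "torsion axis")
    if len(side_j) < len(side_k):
        moving, angle = side_j, -delta
        pivot = system.atoms[j].pos.copy()
    else:
        moving, angle = side_k, delta
        pivot = system.atoms[k].pos.copy()
    rot = _rotation_matrix(axis, angle)
    for idx in moving:
        p = system.atoms[idx].pos
        system.atoms[idx].pos = pivot + rot @ (p - pivot)
    return system


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis (right-handed)."""
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


# -- protein torsions ---------------------------------------------------------

def _atom_index(system: MolecularSystem, ridx: int, name: str) -> int | None:
    for i in system.residues[ridx].atom_indices:
        if system.atoms[i].name == name:
            return i
    return None


def backbone_torsions(system: MolecularSystem) -> list[dict[str, float | None]]:
    """phi, psi, omega, chi1 (degrees) per residue; None where undefined
    (chain termini, missing atoms, Gly/Ala chi1)."""
    out: list[dict[str, float | None]] = []
    for ridx, res in enumerate(system.residues):
        entry: dict[str, float | None] = {"phi": None, "psi": None,
                                          "omega": None, "chi1": None}
        if res.kind != "amino":
            out.append(entry)
            continue
        n = _atom_index(system, ridx, "N")
        ca = _atom_index(system, ridx, "CA")
        c = _atom_index(system, ridx, "C")
        prev_c = prev_ca = next_n = None
        if ridx > 0 and system.residues[ridx - 1].kind == "amino" \
                and system.residues[ridx - 1].chain == res.chain:
            prev_c = _atom_index(system, ridx - 1, "C")
            prev_ca = _atom_index(system, ridx - 1, "CA")
        if ridx + 1 < len(system.residues) and system.residues[ridx + 1].kind == "amino" \
                and system.residues[ridx + 1].chain == res.chain:
            next_n = _atom_index(system, ridx + 1, "N")

        def dih(*idx):
            if any(x is None for x in idx):
                return None
            return measure_dihedral(*(system.atoms[x].pos for x in idx))

        entry["phi"] = dih(prev_c, n, ca, c)
        entry["psi"] = dih(n, ca, c, next_n)
        entry["omega"] = dih(prev_ca, prev_c, n, ca)
        quads = CHI_ATOMS.get(res.name, [])
        if quads:
            entry["chi1"] = dih(*(_atom_index(system, ridx, nm) for nm in quads[0]))
        out.append(entry)
    return out


def measure_chi(system: MolecularSystem, ridx: int) -> list[float]:
    """All defined side-chain chi angles of a residue, in order."""
    out = []
    for quad in CHI_ATOMS.get(system.residues[ridx].name, []):
        idx = [_atom_index(system, ridx, nm) for nm in quad]
        if any(x is None for x in idx):
            break
        out.append(measure_dihedral(*(system.atoms[x].pos for x in idx)))
    return out


# -- mutation -----------------------------------------------------------------

def mutate_residue(system: MolecularSystem, ridx: int, new_name: str,
                   library=None) -> MolecularSystem:
    """Replace the side chain of an amino residue with the ``new_name``
    template, keeping backbone coordinates (N, CA, C, O) fixed.

    The side chain is built from idealised internal coordinates at the
    library's first rotamer (library=None uses the three-state default).
    Hydrogens are (re)built for the mutated residue when the input residue
    carried any hydrogens.
    """
    from .structure_tools import RotamerLibrary, place_missing_hydrogens

    if new_name not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"unknown residue template {new_name!r}")
    res = system.residues[ridx]
    if res.kind != "amino":
        raise ValueError("mutate_residue requires an amino-acid residue")
    if library is None:
        library = RotamerLibrary.three_state()
    chi = library.rotamers(new_name)[0]

    had_h = any(system.atoms[i].element == "H" for i in res.atom_indices)
    keep_names = {"N", "CA", "C", "O", "OXT"}
    remove = [i for i in res.atom_indices if system.atoms[i].name not in keep_names]
    _remove_atoms(system, remove)
    res = system.residues[ridx]
    res.name = new_name
    res.variant = ""

    byname = {system.atoms[i].name: i for i in res.atom_indices}
    for nm in ("N", "CA", "C"):
        if nm not in byname:
            raise ValueError(f"residue missing backbone atom {nm}")
    serial = max(a.serial for a in system.atoms) + 1
    for entry in SIDECHAIN_TEMPLATES[new_name]:
        name, b, a, d, r, theta, tau = entry
        if isinstance(tau, tuple):
            _, k, offset = tau
            base = chi[k - 1] if k - 1 < len(chi) else 180.0
            tau = base + offset
        pos = place_by_internal(system.atoms[byname[d]].pos,
                                system.atoms[byname[a]].pos,
                                system.atoms[byname[b]].pos, r, theta, tau)
        idx = len(system.atoms)
        system.atoms.append(Atom(serial=serial, name=name,
                                 element=_element_of(name), pos=pos,
                                 residue_index=ridx))
        serial += 1
        res.atom_indices.append(idx)
        system.add_bond(byname[b], idx)
        byname[name] = idx
    # ring-closure / extra bonds from the template bond list
    from .data import SIDECHAIN_BONDS
    for a_nm, b_nm in SIDECHAIN_BONDS.get(new_name, []):
        if a_nm in byname and b_nm in byname:
            system.add_bond(byname[a_nm], byname[b_nm])
    system.default_charge_groups()
    if had_h:
        place_missing_hydrogens(system, residues=[ridx])
    return system


def _element_of(atom_name: str) -> str:
    for c in atom_name:
        if c.isalpha():
            return c.upper()
    raise ValueError(f"bad atom name {atom_name!r}")


def _remove_atoms(system: MolecularSystem, indices: list[int]) -> None:
    """Delete atoms and remap bonds, residues and charge groups."""
    doomed = set(indices)
    remap: dict[int, int] = {}
    new_atoms = []
    for i, atom in enumerate(system.atoms):
        if i in doomed:
            continue
        remap[i] = len(new_atoms)
        new_atoms.append(atom)
    system.atoms = new_atoms
    system.bonds = {(min(remap[i], remap[j]), max(remap[i], remap[j]))
                    for i, j in system.bonds if i not in doomed and j not in doomed}
    for res in system.residues:
        res.atom_indices = [remap[i] for i in res.atom_indices if i not in doomed]
    system.charge_groups = [[remap[i] for i in g if i not in doomed]
                            for g in system.charge_groups]
    system.charge_groups = [g for g in system.charge_groups if g]


# -- Ramachandran -------------------------------------------------------------

def _point_in_polygon(x: float, y: float, poly: list[tuple[float, float]]) -> bool:
    inside = False
    n = len(poly)
    for a in range(n):
        x1, y1 = poly[a]
        x2, y2 = poly[(a + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


def classify_ramachandran(phi: float, psi: float) -> str:
    """Classify a backbone (phi, psi) pair as favoured / allowed / outlier
    using the coarse built-in general-case region polygons."""
    for poly in RAMA_FAVOURED:
        if _point_in_polygon(phi, psi, poly):
            return "favoured"
    for poly in RAMA_ALLOWED:
        if _point_in_polygon(phi, psi, poly):
            return "allowed"
    return "outlier"
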