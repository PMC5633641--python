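"""Molecular-mechanics energy and analytic gradient.

Functional form is the AMBER/GAFF family: harmonic bonds and angles
(``k (x - x0)^2`` with the force constant absorbing the 1/2), periodic
cosine torsions ``(Vn/2)(1 + cos(n phi - gamma))``, 12-6 Lennard-Jones with
Lorentz-Berthelot combining, and damped-shifted-force (DSF) electrostatics:
truncated Coulomb with erfc damping plus energy and force shifts so both
vanish continuously at the cutoff, which removes the need for lattice
summation at the cost of a short-ranged approximation.

Units: kcal/mol, Angstrom, elementary charges, radians internally (degrees
never enter this module).  The Coulomb constant is 332.0636 kcal*A/(mol*e^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .data import ELECTRONEGATIVITY, FORMAL_CHARGES
from .molsys import MolecularSystem, Topology

__all__ = [
    "BondParam", "AngleParam", "TorsionParam", "LJParam", "NonbondedSettings",
    "ParameterSet", "EnergyReport", "MissingParameterError",
    "energy_and_gradient", "dsf_pair_energy", "dsf_pair_energy_force",
    "assign_simple_charges", "read_params", "write_params",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)
_TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)


class MissingParameterError(KeyError):
    pass


@dataclass(frozen=True)
class BondParam:
    k: float   # kcal/mol/A^2
    r0: float  # A


@dataclass(frozen=True)
class AngleParam:
    k: float       # kcal/mol/rad^2
    theta0: float  # radians


@dataclass(frozen=True)
class TorsionParam:
    # terms: (barrier Vn/2 in kcal/mol, periodicity n, phase gamma in radians)
    terms: tuple[tuple[float, int, float], ...]


@dataclass(frozen=True)
class LJParam:
    sigma: float    # A
    epsilon: float  # kcal/mol


@dataclass
class NonbondedSettings:
    cutoff: float = 9.0        # A
    dsf_alpha: float = 0.2     # 1/A
    scale14_lj: float = 0.5
    scale14_coul: float = 1.0 / 1.2
    coulomb_const: float = COULOMB_CONSTANT


@dataclass
class EnergyReport:
    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    improper: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.torsion + self.improper + self.lj + self.coulomb

    def as_table(self) -> str:
        rows = [("bond", self.bond), ("angle", self.angle),
                ("torsion", self.torsion), ("improper", self.improper),
                ("lj", self.lj), ("coulomb", self.coulomb),
                ("total", self.total)]
        return "\n".join(f"{name:<10s} {val:16.6f} kcal/mol" for name, val in rows)


@dataclass
class ParameterSet:
    """Force-field parameters keyed by atom-type label.

    Torsion lookups fall back to wildcard keys with ``"X"`` in the outer
    (and finally all) positions; bond/angle lookups are symmetric under
    reversal.
    """

    bonds: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)
    torsions: dict[tuple[str, str, str, str], TorsionParam] = field(default_factory=dict)
    impropers: dict[tuple[str, str, str, str], TorsionParam] = field(default_factory=dict)
    lj: dict[str, LJParam] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)

    def bond(self, t1: str, t2: str) -> BondParam:
        for key in ((t1, t2), (t2, t1)):
            if key in self.bonds:
                return self.bonds[key]
        raise MissingParameterError(f"bond parameters missing for {(t1, t2)}")

    def angle(self, t1: str, t2: str, t3: str) -> AngleParam:
        for key in ((t1, t2, t3), (t3, t2, t1), ("X", t2, "X")):
            if key in self.angles:
                return self.angles[key]
        raise MissingParameterError(f"angle parameters missing for {(t1, t2, t3)}")

    def torsion(self, t1: str, t2: str, t3: str, t4: str) -> TorsionParam | None:
        for key in ((t1, t2, t3, t4), (t4, t3, t2, t1),
                    ("X", t2, t3, "X"), ("X", t3, t2, "X"),
                    ("X", "X", "X", "X")):
            if key in self.torsions:
                return self.torsions[key]
        return None

    def improper(self, t1: str, t2: str, tc: str, t3: str) -> TorsionParam | None:
        for key in ((t1, t2, tc, t3), ("X", "X", tc, "X")):
            if key in self.impropers:
                return self.impropers[key]
        return None

    def lj_param(self, t: str) -> LJParam:
        if t in self.lj:
            return self.lj[t]
        raise MissingParameterError(f"LJ parameters missing for type {t!r}")


# -- DSF electrostatics -------------------------------------------------------

def _dsf_shifts(settings: NonbondedSettings) -> tuple[float, float]:
    rc, a = settings.cutoff, settings.dsf_alpha
    e_shift = erfc(a * rc) / rc
    f_shift = e_shift / rc + _TWO_OVER_SQRT_PI * a * math.exp(-(a * rc) ** 2) / rc
    return float(e_shift), float(f_shift)


def dsf_pair_energy(q1: float, q2: float, r: float,
                    settings: NonbondedSettings | None = None) -> float:
    """Damped-shifted-force pair energy; zero (with zero force) at and beyond
    the cutoff."""
    return dsf_pair_energy_force(q1, q2, r, settings)[0]


def dsf_pair_energy_force(q1: float, q2: float, r: float,
                          settings: NonbondedSettings | None = None) -> tuple[float, float]:
    """Return (E, dE/dr) for one charge pair under the DSF scheme."""
    if settings is None:
        settings = NonbondedSettings()
    if r <= 0:
        raise ValueError("r must be positive")
    if r > settings.cutoff:
        return 0.0, 0.0
    a = settings.dsf_alpha
    e_shift, f_shift = _dsf_shifts(settings)
    c = settings.coulomb_const * q1 * q2
    e = c * (erfc(a * r) / r - e_shift + f_shift * (r - settings.cutoff))
    de = c * (-erfc(a * r) / r ** 2 - _TWO_OVER_SQRT_PI * a * math.exp(-(a * r) ** 2) / r
              + f_shift)
    return float(e), float(de)


# -- energy and gradient ------------------------------------------------------

def _types(system: MolecularSystem) -> list[str]:
    return [a.ff_type or a.element for a in system.atoms]


def energy_and_gradient(system: MolecularSystem, topology: Topology,
                        params: ParameterSet,
                        settings: NonbondedSettings | None = None,
                        coords: np.ndarray | None = None,
                        ) -> tuple[EnergyReport, np.ndarray]:
    """Total potential energy by term and the exact analytic gradient
    (kcal/mol/A, shape (N, 3)).

    ``coords`` overrides the system's stored coordinates without mutating
    them (used by the minimiser and MD integrator).  An orthorhombic
    ``system.box`` triggers minimum-image distances for nonbonded pairs.
    """
    if settings is None:
        settings = NonbondedSettings()
    xyz = system.coords() if coords is None else np.asarray(coords, float)
    n = len(system.atoms)
    grad = np.zeros((n, 3))
    rep = EnergyReport()
    types = _types(system)

    # bonds
    for i, j in topology.bonds:
        p = params.bond(types[i], types[j])
        d = xyz[i] - xyz[j]
        r = float(np.linalg.norm(d))
        rep.bond += p.k * (r - p.r0) ** 2
        g = 2.0 * p.k * (r - p.r0) / r * d
        grad[i] += g
        grad[j] -= g

    # angles
    for i, j, k in topology.angles:
        p = params.angle(types[i], types[j], types[k])
        u = xyz[i] - xyz[j]
        v = xyz[k] - xyz[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cos_t = float(np.dot(u, v) / (nu * nv))
        cos_t = max(-1.0, min(1.0, cos_t))
        theta = math.acos(cos_t)
        sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-16))
        rep.angle += p.k * (theta - p.theta0) ** 2
        dE = 2.0 * p.k * (theta - p.theta0)
        uh, vh = u / nu, v / nv
        di = (cos_t * uh - vh) / (nu * sin_t)
        dk = (cos_t * vh - uh) / (nv * sin_t)
        grad[i] += dE * di
        grad[k] += dE * dk
        grad[j] -= dE * (di + dk)

    # proper torsions + impropers
    for quads, table, kind in ((topology.torsions, "torsion", "proper"),
                               (topology.impropers, "improper", "improper")):
        for quad in quads:
            i, j, k, l = quad
            if kind == "proper":
                p = params.torsion(types[i], types[j], types[k], types[l])
            else:
                p = params.improper(types[i], types[j], types[k], types[l])
            if p is None:
                continue
            e, gi, gj, gk, gl = _torsion_term(xyz[i], xyz[j], xyz[k], xyz[l], p)
            if kind == "proper":
                rep.torsion += e
            else:
                rep.improper += e
            grad[i] += gi
            grad[j] += gj
            grad[k] += gk
            grad[l] += gl

    # nonbonded
    e_lj, e_coul = _nonbonded(system, topology, params, settings, xyz, grad, types)
    rep.lj += e_lj
    rep.coulomb += e_coul
    return rep, grad


def _torsion_term(ri, rj, rk, rl, p: TorsionParam):
    b1 = rj - ri
    b2 = rk - rj
    b3 = rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = float(np.linalg.norm(b2))
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    if n1sq < 1e-18 or n2sq < 1e-18:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    phi = math.atan2(float(np.dot(np.cross(n1, n2), b2 / b2n)), float(np.dot(n1, n2)))
    e = 0.0
    dE = 0.0
    for barrier, nper, gamma in p.terms:
        e += barrier * (1.0 + math.cos(nper * phi - gamma))
        dE += -barrier * nper * math.sin(nper * phi - gamma)
    dphi_dri = -(b2n / n1sq) * n1
    dphi_drl = (b2n / n2sq) * n2
    s = float(np.dot(b1, b2)) / (b2n * b2n)
    t = float(np.dot(b3, b2)) / (b2n * b2n)
    dphi_drj = -(1.0 + s) * dphi_dri + t * dphi_drl
    dphi_drk = s * dphi_dri - (1.0 + t) * dphi_drl
    return e, dE * dphi_dri, dE * dphi_drj, dE * dphi_drk, dE * dphi_drl


def _nonbonded(system, topology, params, settings, xyz, grad, types):
    n = len(system.atoms)
    if n < 2:
        return 0.0, 0.0
    ii, jj = np.triu_indices(n, k=1)
    keep = np.ones(len(ii), dtype=bool)
    scale_lj = np.ones(len(ii))
    scale_coul = np.ones(len(ii))
    pair_index = {(int(a), int(b)): m for m, (a, b) in enumerate(zip(ii, jj))}
    for (a, b) in topology.exclusions:
        keep[pair_index[(min(a, b), max(a, b))]] = False
    for (a, b) in topology.scaled14:
        m = pair_index[(min(a, b), max(a, b))]
        scale_lj[m] = settings.scale14_lj
        scale_coul[m] = settings.scale14_coul
    ii, jj = ii[keep], jj[keep]
    scale_lj, scale_coul = scale_lj[keep], scale_coul[keep]

    d = xyz[ii] - xyz[jj]
    if system.box is not None:
        box = np.asarray(system.box, float)
        d -= box * np.round(d / box)
    r2 = np.einsum("ij,ij->i", d, d)
    within = r2 < settings.cutoff ** 2
    ii, jj, d, r2 = ii[within], jj[within], d[within], r2[within]
    scale_lj, scale_coul = scale_lj[within], scale_coul[within]
    if len(ii) == 0:
        return 0.0, 0.0
    r = np.sqrt(r2)

    sig = np.array([params.lj_param(t).sigma for t in types])
    eps = np.array([params.lj_param(t).epsilon for t in types])
    sij = 0.5 * (sig[ii] + sig[jj])
    eij = np.sqrt(eps[ii] * eps[jj]) * scale_lj
    sr6 = (sij ** 2 / r2) ** 3
    e_lj_pair = 4.0 * eij * (sr6 ** 2 - sr6)
    de_lj = 4.0 * eij * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r

    q = np.array([a.charge for a in system.atoms])
    qq = q[ii] * q[jj] * scale_coul * settings.coulomb_const
    a_ = settings.dsf_alpha
    rc = settings.cutoff
    e_shift, f_shift = _dsf_shifts(settings)
    erfc_r = erfc(a_ * r)
    e_coul_pair = qq * (erfc_r / r - e_shift + f_shift * (r - rc))
    de_coul = qq * (-erfc_r / r2 - _TWO_OVER_SQRT_PI * a_ * np.exp(-(a_ * r) ** 2) / r
                    + f_shift)

    de = (de_lj + de_coul) / r
    gpair = de[:, None] * d
    np.add.at(grad, ii, gpair)
    np.add.at(grad, jj, -gpair)
    return float(np.sum(e_lj_pair)), float(np.sum(e_coul_pair))


def assign_atom_types(system: MolecularSystem) -> MolecularSystem:
    """Element-based atom typing with one refinement: hydrogens bonded to N
    or O get the polar type ``HP``, which carries no Lennard-Jones volume
    (the AMBER convention that makes hydrogen bonding possible)."""
    adj = system.neighbours()
    for i, atom in enumerate(system.atoms):
        t = atom.element
        if t == "H" and any(system.atoms[j].element in ("N", "O") for j in adj[i]):
            t = "HP"
        atom.ff_type = t
    return system


# -- simple charge assignment -------------------------------------------------

def assign_simple_charges(system: MolecularSystem, kappa: float = 0.16) -> MolecularSystem:
    """Assign partial charges by one-shot electronegativity equalisation over
    bonds, then shift each charge group so it sums to its formal charge.

    ``q_i = kappa * sum_j (chi_j - chi_i)`` over bonded neighbours j; the
    more electronegative end of each bond acquires negative charge.  Formal
    charges come from the residue table (charged side chains) and default
    to zero.
    """
    adj = system.neighbours()
    for i, atom in enumerate(system.atoms):
        chi_i = ELECTRONEGATIVITY.get(atom.element, 2.5)
        q = 0.0
        for j in adj[i]:
            chi_j = ELECTRONEGATIVITY.get(system.atoms[j].element, 2.5)
            q += kappa * (chi_j - chi_i)
        atom.charge = q
    if not system.charge_groups:
        system.default_charge_groups()
    for group in system.charge_groups:
        ridx = system.atoms[group[0]].residue_index
        res = system.residues[ridx]
        formal = float(FORMAL_CHARGES.get(res.name, 0)) if res.kind == "amino" else 0.0
        total = sum(system.atoms[i].charge for i in group)
        shift = (formal - total) / len(group)
        for i in group:
            system.atoms[i].charge += shift
    return system


# -- parameter file dialect ---------------------------------------------------

_HEADER = "# mmkit-params v1"


def write_params(params: ParameterSet) -> str:
    """Serialise to the human-readable key-value dialect (one record per
    line; torsion terms repeat the key)."""
    lines = [_HEADER]
    for (t1, t2), p in sorted(params.bonds.items()):
        lines.append(f"bond {t1} {t2} {p.k:.6g} {p.r0:.6g}")
    for (t1, t2, t3), p in sorted(params.angles.items()):
        lines.append(f"angle {t1} {t2} {t3} {p.k:.6g} {math.degrees(p.theta0):.6g}")
    for key, p in sorted(params.torsions.items()):
        for barrier, nper, gamma in p.terms:
            lines.append("torsion " + " ".join(key) +
                         f" {barrier:.6g} {nper} {math.degrees(gamma):.6g}")
    for key, p in sorted(params.impropers.items()):
        for barrier, nper, gamma in p.terms:
            lines.append("improper " + " ".join(key) +
                         f" {barrier:.6g} {nper} {math.degrees(gamma):.6g}")
    for t, p in sorted(params.lj.items()):
        lines.append(f"lj {t} {p.sigma:.6g} {p.epsilon:.6g}")
    for t, qv in sorted(params.charges.items()):
        lines.append(f"charge {t} {qv:.6g}")
    return "\n".join(lines) + "\n"


def read_params(text: str) -> ParameterSet:
    """Parse the dialect written by :func:`write_params`.  Angles and torsion
    phases are degrees on disk, radians in memory."""
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# mmkit-params"):
        raise ValueError("missing parameter-file header '# mmkit-params v1'")
    ps = ParameterSet()
    tor_acc: dict[tuple, list] = {}
    imp_acc: dict[tuple, list] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.split("#")[0].strip()
        if not line:
            continue
        f = line.split()
        try:
            if f[0] == "bond":
                ps.bonds[(f[1], f[2])] = BondParam(float(f[3]), float(f[4]))
            elif f[0] == "angle":
                ps.angles[(f[1], f[2], f[3])] = AngleParam(float(f[4]), math.radians(float(f[5])))
            elif f[0] == "torsion":
                tor_acc.setdefault(tuple(f[1:5]), []).append(
                    (float(f[5]), int(f[6]), math.radians(float(f[7]))))
            elif f[0] == "improper":
                imp_acc.setdefault(tuple(f[1:5]), []).append(
                    (float(f[5]), int(f[6]), math.radians(float(f[7]))))
            elif f[0] == "lj":
                ps.lj[f[1]] = LJParam(float(f[2]), float(f[3]))
            elif f[0] == "charge":
                ps.charges[f[1]] = float(f[2])
            elif f[0] == "mass":
                pass  # accepted for forward compatibility
            else:
                raise ValueError(f"unknown record {f[0]!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"parameter file line {lineno}: {exc}") from None
    for key, terms in tor_acc.items():
        ps.torsions[key] = TorsionParam(tuple(terms))
    for key, terms in imp_acc.items():
        ps.impropers[key] = TorsionParam(tuple(terms))
    return ps
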