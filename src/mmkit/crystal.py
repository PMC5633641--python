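"""Crystal lattice handling: unit cells, fractional coordinates, supercell
expansion and lattice-sum energies with neutral charge groups.

The infinite crystal is approximated by an n x n x n grid of copies of the
unit cell (default 5, i.e. 125 cells) with the reference cell at the centre.
Electrostatic truncation operates on neutral charge groups: a pair of groups
enters the inter-image sum whole, or not at all, decided by the distance
between the group geometric centres against the nonbonded cutoff.  Because
every group is (near-)neutral, the truncated sum converges without Ewald
machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (NonbondedSettings, ParameterSet, energy_and_gradient)
from .minimize import MinimizationResult, MinimizerOptions, minimize_vector
from .molsys import MolecularSystem, Topology

__all__ = [
    "UnitCell", "CrystalSystem", "LatticeEnergyBreakdown", "CellCollapseError",
    "frac_to_cart", "cart_to_frac", "build_supercell", "lattice_energy",
    "optimize_crystal",
]


class CellCollapseError(RuntimeError):
    pass


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0   # degrees
    beta: float = 90.0
    gamma: float = 90.0
    # symmetry operators in fractional space: (3x3 rotation, translation)
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if not self.symmetry_ops:
            self.symmetry_ops = [(np.eye(3), np.zeros(3))]
        if self.volume < 1e-9:
            raise ValueError("degenerate cell: volume ~ 0")

    @property
    def matrix(self) -> np.ndarray:
        """Column vectors of the cell basis; a along x, b in the xy plane."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v = 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(v, 0.0))


def frac_to_cart(cell: UnitCell, frac: np.ndarray) -> np.ndarray:
    return np.asarray(frac, float) @ cell.matrix.T


def cart_to_frac(cell: UnitCell, cart: np.ndarray) -> np.ndarray:
    return np.asarray(cart, float) @ np.linalg.inv(cell.matrix).T


@dataclass
class CrystalSystem:
    cell: UnitCell
    contents: MolecularSystem   # full cell contents, Cartesian A


@dataclass
class LatticeEnergyBreakdown:
    intra_cell: float
    inter_image: float

    @property
    def total(self) -> float:
        return self.intra_cell + self.inter_image


def build_supercell(n: int = 5) -> list[tuple[int, int, int]]:
    """Integer translations of an n x n x n supercell centred on (0,0,0)."""
    if n < 1 or n % 2 == 0:
        raise ValueError("supercell size must be a positive odd integer")
    h = n // 2
    rng = range(-h, h + 1)
    return [(i, j, k) for i in rng for j in rng for k in rng]


def _check_groups_neutral(system: MolecularSystem, force: bool) -> None:
    charged = any(abs(a.charge) > 0 for a in system.atoms)
    if not charged:
        return
    for g in system.charge_groups:
        s = sum(system.atoms[i].charge for i in g)
        if abs(s) > 1e-6:
            msg = (f"charge group {g} sums to {s:.6f} e; neutral-group "
                   "electrostatic truncation requires neutral groups")
            if force:
                import warnings
                warnings.warn(msg)
            else:
                raise ValueError(msg + " (pass force=True to override)")


def lattice_energy(crystal: CrystalSystem, topology: Topology,
                   params: ParameterSet,
                   settings: NonbondedSettings | None = None,
                   n: int = 5, force: bool = False,
                   coords: np.ndarray | None = None) -> LatticeEnergyBreakdown:
    """Lattice energy per unit cell over the n^3 supercell.

    intra_cell is the full force-field energy of the cell contents;
    inter_image sums LJ plus plain-Coulomb interactions between the central
    cell and every image, group pairs gated by group-centre cutoff, halved
    to count each cross-cell interaction once.
    """
    if settings is None:
        settings = NonbondedSettings()
    system = crystal.contents
    _check_groups_neutral(system, force)
    rep, _ = energy_and_gradient(system, topology, params, settings, coords=coords)
    xyz = system.coords() if coords is None else np.asarray(coords, float)
    groups = system.charge_groups or [[i for i in range(len(system.atoms))]]
    centres = np.array([xyz[g].mean(axis=0) for g in groups])
    q = np.array([a.charge for a in system.atoms])
    types = [a.ff_type or a.element for a in system.atoms]
    sig = np.array([params.lj_param(t).sigma for t in types])
    eps = np.array([params.lj_param(t).epsilon for t in types])
    M = crystal.cell.matrix
    trips = np.array([t for t in build_supercell(n) if t != (0, 0, 0)],
                     float).reshape(-1, 3)
    shifts = trips @ M.T                                   # (n^3-1, 3)
    # gate whole charge-group pairs by centre distance, vectorised
    sep = (centres[None, :, None, :] + shifts[:, None, None, :]
           - centres[None, None, :, :])                    # (S, Gj, Gi, 3)
    within = np.linalg.norm(sep, axis=-1) < settings.cutoff
    inter = 0.0
    for s_idx, gj, gi in zip(*np.nonzero(within)):
        g1, g2 = groups[gi], groups[gj]
        d = xyz[g1][:, None, :] - (xyz[g2][None, :, :] + shifts[s_idx])
        r2 = np.einsum("ijk,ijk->ij", d, d)
        r = np.sqrt(r2)
        s_ij = 0.5 * (sig[g1][:, None] + sig[g2][None, :])
        e_ij = np.sqrt(eps[g1][:, None] * eps[g2][None, :])
        sr6 = (s_ij ** 2 / r2) ** 3
        inter += float(np.sum(4.0 * e_ij * (sr6 ** 2 - sr6)))
        inter += float(settings.coulomb_const *
                       np.sum(q[g1][:, None] * q[g2][None, :] / r))
    return LatticeEnergyBreakdown(intra_cell=rep.total, inter_image=0.5 * inter)


def optimize_crystal(crystal: CrystalSystem, topology: Topology,
                     params: ParameterSet,
                     settings: NonbondedSettings | None = None,
                     optimise_cell: bool = True, n: int = 5,
                     options: MinimizerOptions | None = None,
                     ) -> tuple[CrystalSystem, MinimizationResult]:
    """Jointly minimise atomic positions (as fractional coordinates) and,
    optionally, the six cell parameters.

    All gradients are central finite differences on the lattice energy;
    the conjugate-gradient minimiser drives the search.  A cell whose volume
    falls below 20% of the starting volume aborts with a diagnostic.
    """
    if options is None:
        options = MinimizerOptions(method="cg_powell_beale", grad_tol=0.01,
                                   max_iter=100)
    system = crystal.contents
    natom = len(system.atoms)
    cell0 = crystal.cell
    frac0 = cart_to_frac(cell0, system.coords())
    v0 = cell0.volume
    cellvec0 = np.array([cell0.a, cell0.b, cell0.c,
                         cell0.alpha, cell0.beta, cell0.gamma])
    x0 = np.concatenate([frac0.ravel(), cellvec0]) if optimise_cell else frac0.ravel()

    def unpack(x):
        frac = x[:3 * natom].reshape(natom, 3)
        if optimise_cell:
            a, b, c, al, be, ga = x[3 * natom:]
            if min(a, b, c) <= 0.05 or not all(1.0 < v < 179.0 for v in (al, be, ga)):
                return None, None
            cell = UnitCell(a, b, c, al, be, ga, symmetry_ops=cell0.symmetry_ops)
        else:
            cell = cell0
        return cell, frac

    def energy_of(x):
        cell, frac = unpack(x)
        if cell is None or cell.volume < 0.2 * v0:
            return math.inf
        trial = CrystalSystem(cell=cell, contents=system)
        return lattice_energy(trial, topology, params, settings, n=n,
                              coords=frac_to_cart(cell, frac)).total

    def fun(x):
        f = energy_of(x)
        g = np.zeros_like(x)
        if not math.isfinite(f):
            return f, g
        for k in range(len(x)):
            h = 1e-4 * max(abs(x[k]), 1.0)
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            g[k] = (energy_of(xp) - energy_of(xm)) / (2 * h)
        return f, g

    res = minimize_vector(fun, x0, options)
    cell, frac = unpack(res.coords)
    if cell is None or cell.volume < 0.2 * v0:
        raise CellCollapseError(
            f"cell volume collapsed below 20% of the start ({v0:.3f} A^3)")
    out = CrystalSystem(cell=cell, contents=_with_coords(system, frac_to_cart(cell, frac)))
    res.coords = out.contents.coords()
    if res.energy > lattice_energy(crystal, topology, params, settings, n=n).total + 1e-9:
        res.message = (res.message + "; final energy above start").strip("; ")
    return out, res


def _with_coords(system: MolecularSystem, xyz: np.ndarray) -> MolecularSystem:
    import copy
    new = copy.deepcopy(system)
    new.set_coords(xyz)
    return new


def apply_symmetry(cell: UnitCell, frac: np.ndarray,
                   op: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Apply a fractional-space symmetry operator to fractional coordinates."""
    R, t = op
    return frac @ np.asarray(R, float).T + np.asarray(t, float)
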