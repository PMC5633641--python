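"""Statistical pair potentials for pose scoring.

A potential of mean force (PMF) is obtained by Boltzmann inversion of the
radial distribution of distances between atoms of two types,

    e(r) = -kB T ln( g_obs(r) / g_ref(r) ),

relative to a reference state: either an explicit bulk histogram
(``bulk_ratio`` mode) or the distance-scaled ideal-gas reference of the
DFIRE family, ``g_ref(r) proportional to r^exponent`` (default exponent
1.61).  Tables are binned (0.2 A default), capped at +e_max where the
observed count vanishes, and shifted so the last bin inside the cutoff is
zero.  A pose score is the sum of table lookups (linear interpolation
between bin centres) over all receptor-ligand atom pairs within the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import KB
from .molsys import MolecularSystem

__all__ = [
    "DistanceHistogram", "PairPotentialTable", "PoseScore",
    "pmf_from_histogram", "score_pose", "transform_pose", "align_three_point",
    "write_table", "read_table", "type_by_element", "DFIRE_EXPONENT",
]

DFIRE_EXPONENT = 1.61
DEFAULT_EMAX = 3.0  # kcal/mol cap for empty observed bins


@dataclass
class DistanceHistogram:
    type_pair: tuple[str, str]
    bin_edges: np.ndarray     # length nbins + 1, uniform, A
    counts: np.ndarray        # length nbins, non-negative

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts length must equal number of bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PairPotentialTable:
    type_pair: tuple[str, str]
    bin_edges: np.ndarray
    energies: np.ndarray      # kcal/mol per bin
    cutoff: float
    reference_mode: str = "bulk_ratio"   # bulk_ratio | distance_scaled

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def interpolate(self, r: float) -> float:
        """Energy at distance r: linear between bin centres, clamped to the
        first bin below, exactly zero at and beyond the cutoff."""
        if r >= self.cutoff:
            return 0.0
        c = self.centres
        if r <= c[0]:
            return float(self.energies[0])
        if r >= c[-1]:
            return float(self.energies[-1])
        k = int(np.searchsorted(c, r) - 1)
        w = (r - c[k]) / (c[k + 1] - c[k])
        return float((1 - w) * self.energies[k] + w * self.energies[k + 1])


@dataclass
class PoseScore:
    total: float
    pair_contributions: list[tuple[int, int, float, float]] = field(default_factory=list)

    def report_tsv(self) -> str:
        lines = ["# i\tj\tr_A\tenergy"]
        for i, j, r, e in self.pair_contributions:
            lines.append(f"{i}\t{j}\t{r:.3f}\t{e:.4f}")
        lines.append(f"# total\t\t\t{self.total:.4f}")
        return "\n".join(lines) + "\n"


def pmf_from_histogram(hist: DistanceHistogram,
                       reference: DistanceHistogram | None = None,
                       distance_scaled_exponent: float | None = None,
                       T: float = 300.0,
                       e_max: float = DEFAULT_EMAX,
                       cutoff: float | None = None) -> PairPotentialTable:
    """Boltzmann-invert an observed distance histogram against a reference.

    Exactly one of ``reference`` (bulk-ratio mode) or
    ``distance_scaled_exponent`` (DFIRE-style mode, g_ref ~ r^exponent)
    must be given.  Energies are shifted so the last bin inside the cutoff
    is zero; bins with zero observed counts are capped at ``+e_max``.
    """
    if (reference is None) == (distance_scaled_exponent is None):
        raise ValueError("give either a reference histogram or a distance-scaled exponent")
    if hist.counts.sum() <= 0:
        raise ValueError("observed histogram is empty")
    centres = hist.centres
    if reference is not None:
        if reference.counts.sum() <= 0:
            raise ValueError("reference histogram is empty (zero everywhere)")
        if len(reference.counts) != len(hist.counts):
            raise ValueError("observed and reference binning differ")
        g_ref = reference.counts / reference.counts.sum()
        mode = "bulk_ratio"
    else:
        g_ref = centres ** distance_scaled_exponent
        g_ref = g_ref / g_ref.sum()
        mode = "distance_scaled"
    g_obs = hist.counts / hist.counts.sum()
    kt = KB * T
    e = np.full(len(centres), e_max)
    ok = (g_obs > 0) & (g_ref > 0)
    e[ok] = -kt * np.log(g_obs[ok] / g_ref[ok])
    np.clip(e, -np.inf, e_max, out=e)
    cutoff = float(hist.bin_edges[-1]) if cutoff is None else cutoff
    inside = centres < cutoff
    if inside.any():
        e = e - e[inside][-1]
    return PairPotentialTable(type_pair=hist.type_pair, bin_edges=hist.bin_edges,
                              energies=e, cutoff=cutoff, reference_mode=mode)


# -- pose scoring -------------------------------------------------------------

def type_by_element(system: MolecularSystem, indices=None) -> list[str]:
    """Minimal atom typing: the element symbol (polar hydrogens are typed
    'HP' when bonded to N or O)."""
    adj = system.neighbours()
    idx = range(len(system.atoms)) if indices is None else indices
    out = []
    for i in idx:
        a = system.atoms[i]
        t = a.element
        if t == "H" and any(system.atoms[j].element in ("N", "O") for j in adj[i]):
            t = "HP"
        out.append(t)
    return out


def score_pose(protein_xyz: np.ndarray, protein_types: list[str],
               ligand_xyz: np.ndarray, ligand_types: list[str],
               tables: dict[tuple[str, str], PairPotentialTable],
               default_zero: bool = True) -> PoseScore:
    """Sum of pair-potential lookups over all receptor-ligand atom pairs
    within each table's cutoff, with per-pair decomposition.

    A missing type pair falls back to a zero table with a warning when
    ``default_zero`` is true, and raises otherwise.
    """
    protein_xyz = np.asarray(protein_xyz, float)
    ligand_xyz = np.asarray(ligand_xyz, float)
    contributions = []
    total = 0.0
    warned: set[tuple[str, str]] = set()
    for i, (pi, ti) in enumerate(zip(protein_xyz, protein_types)):
        for j, (pj, tj) in enumerate(zip(ligand_xyz, ligand_types)):
            table = tables.get((ti, tj)) or tables.get((tj, ti))
            if table is None:
                key = (ti, tj)
                if not default_zero:
                    raise KeyError(f"no pair potential for type pair {key}")
                if key not in warned and (tj, ti) not in warned:
                    import warnings
                    warnings.warn(f"no pair potential for {key}; contributing zero")
                    warned.add(key)
                continue
            r = float(np.linalg.norm(pi - pj))
            if r >= table.cutoff:
                continue
            e = table.interpolate(r)
            total += e
            contributions.append((i, j, r, e))
    return PoseScore(total=total, pair_contributions=contributions)


def score_pose_system(system: MolecularSystem, protein_idx: list[int],
                      ligand_idx: list[int],
                      tables: dict[tuple[str, str], PairPotentialTable]) -> PoseScore:
    xyz = system.coords()
    types = type_by_element(system)
    return score_pose(xyz[protein_idx], [types[i] for i in protein_idx],
                      xyz[ligand_idx], [types[i] for i in ligand_idx], tables)


def transform_pose(ligand_xyz: np.ndarray, translation=(0.0, 0.0, 0.0),
                   rotation: np.ndarray | None = None,
                   about_centroid: bool = True) -> np.ndarray:
    """Rigidly transform ligand coordinates: rotate (about the centroid by
    default), then translate.  The rotation must be proper (det = +1)."""
    xyz = np.asarray(ligand_xyz, float).copy()
    if rotation is not None:
        R = np.asarray(rotation, float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-8 \
                or np.max(np.abs(R @ R.T - np.eye(3))) > 1e-8:
            raise ValueError("rotation must be a proper orthogonal 3x3 matrix")
        pivot = xyz.mean(axis=0) if about_centroid else np.zeros(3)
        xyz = (xyz - pivot) @ R.T + pivot
    return xyz + np.asarray(translation, float)


# -- three-point alignment ----------------------------------------------------

def _triplet_frame(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame from three points: x along 1->2,
    z normal to the 1-2-3 plane, y completing (in-plane, towards point 3)."""
    x = p2 - p1
    nx = np.linalg.norm(x)
    if nx < 1e-10:
        raise ValueError("alignment points 1 and 2 coincide")
    x = x / nx
    v = p3 - p1
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nz < 1e-10:
        raise ValueError("alignment triplet is collinear")
    z = z / nz
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def align_three_point(mobile_xyz: np.ndarray, target_xyz: np.ndarray,
                      triplet_mobile: tuple[int, int, int],
                      triplet_target: tuple[int, int, int]) -> np.ndarray:
    """Superpose three chosen atoms: translate mobile point 1 onto target
    point 1, rotate the 1->2 direction onto the target 1->2 direction, then
    rotate about it so mobile point 3 falls in the target 1-2-3 plane (same
    side).  The transform is rigid; non-triplet atoms follow along."""
    mobile_xyz = np.asarray(mobile_xyz, float)
    target_xyz = np.asarray(target_xyz, float)
    pm = [mobile_xyz[i] for i in triplet_mobile]
    pt = [target_xyz[i] for i in triplet_target]
    Fm = _triplet_frame(*pm)
    Ft = _triplet_frame(*pt)
    R = Ft @ Fm.T
    return (mobile_xyz - pm[0]) @ R.T + pt[0]


# -- table file format --------------------------------------------------------

def write_table(table: PairPotentialTable) -> str:
    """Header (pair, bin width, cutoff, mode) then rows (bin centre, energy)."""
    width = float(table.bin_edges[1] - table.bin_edges[0])
    lines = [
        "# mmkit-pairpotential v1",
        f"# pair {table.type_pair[0]} {table.type_pair[1]}",
        f"# bin_width {width:.6g}",
        f"# cutoff {table.cutoff:.6g}",
        f"# mode {table.reference_mode}",
    ]
    for c, e in zip(table.centres, table.energies):
        lines.append(f"{c:.4f}\t{e:.6f}")
    return "\n".join(lines) + "\n"


def read_table(text: str) -> PairPotentialTable:
    pair = ("?", "?")
    width = cutoff = None
    mode = "bulk_ratio"
    centres, energies = [], []
    for line in text.splitlines():
        if line.startswith("#"):
            f = line[1:].split()
            if f and f[0] == "pair":
                pair = (f[1], f[2])
            elif f and f[0] == "bin_width":
                width = float(f[1])
            elif f and f[0] == "cutoff":
                cutoff = float(f[1])
            elif f and f[0] == "mode":
                mode = f[1]
        elif line.strip():
            c, e = line.split()
            centres.append(float(c))
            energies.append(float(e))
    if width is None or cutoff is None or not centres:
        raise ValueError("malformed pair-potential table")
    edges = np.array(centres) - width / 2
    edges = np.append(edges, centres[-1] + width / 2)
    return PairPotentialTable(type_pair=pair, bin_edges=edges,
                              energies=np.array(energies), cutoff=cutoff,
                              reference_mode=mode)
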