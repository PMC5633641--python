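"""Z-matrix conversions, torsion editing, mutation, Ramachandran."""

import math

import numpy as np
import pytest

from mmkit.fixtures import make_polyala
from mmkit.internal_coords import (DegenerateGeometryError, RingTorsionError,
                                   ZMatrix, ZMatrixRow, backbone_torsions,
                                   cartesian_to_zmatrix, classify_ramachandran,
                                   measure_chi, measure_dihedral,
                                   mutate_residue, read_zmatrix_text,
                                   set_torsion, write_zmatrix_text,
                                   zmatrix_to_cartesian)
from mmkit.molsys import measure_angle, read_xyz


class TestMeasureDihedral:
    def test_cis_is_zero(self):
        assert measure_dihedral((1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(0.0)

    def test_trans_is_180(self):
        assert abs(measure_dihedral((-1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0))) == pytest.approx(180.0)

    def test_plus_ninety_matches_atan2_formula(self):
        # independent evaluation via the explicit atan2 construction
        p1, p2, p3, p4 = map(np.array, [(0., 1, 0), (0., 0, 0), (1., 0, 0), (1., 0, 1)])
        b0, b1, b2 = p1 - p2, (p3 - p2) / np.linalg.norm(p3 - p2), p4 - p3
        v = b0 - np.dot(b0, b1) * b1
        w = b2 - np.dot(b2, b1) * b1
        expected = math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
        assert measure_dihedral(p1, p2, p3, p4) == pytest.approx(expected)
        assert expected == pytest.approx(90.0)

    def test_reversal_symmetry(self):
        """IUPAC dihedrals are invariant under reversing the atom order."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.uniform(-3, 3, (4, 3))
            try:
                fwd = measure_dihedral(*p)
            except DegenerateGeometryError:
                continue
            assert measure_dihedral(*p[::-1]) == pytest.approx(fwd, abs=1e-10)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(1)
        p = rng.uniform(-2, 2, (4, 3))
        ref = measure_dihedral(*p)
        R = Rotation.random(random_state=2).as_matrix()
        q = p @ R.T + np.array([5.0, -3.0, 1.0])
        assert measure_dihedral(*q) == pytest.approx(ref, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            measure_dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0))


class TestZMatrixToCartesian:
    def test_frame_convention(self):
        z = ZMatrix(rows=[
            ZMatrixRow("O"),
            ZMatrixRow("H", 0, bond=0.96),
            ZMatrixRow("H", 0, 1, bond=0.96, angle=104.5),
        ])
        xyz = zmatrix_to_cartesian(z)
        assert np.allclose(xyz[0], 0.0)
        assert xyz[1][1] == xyz[1][2] == 0.0 and xyz[1][0] > 0
        assert xyz[2][1] > 0 and abs(xyz[2][2]) < 1e-12
        assert measure_angle(xyz[1], xyz[0], xyz[2]) == pytest.approx(104.5)

    def test_internal_values_reproduced(self):
        z = ZMatrix(rows=[
            ZMatrixRow("C"),
            ZMatrixRow("C", 0, bond=1.5),
            ZMatrixRow("C", 1, 0, bond=1.5, angle=90.0),
            ZMatrixRow("C", 2, 1, 0, bond=1.4, angle=110.0, dihedral=180.0),
        ])
        xyz = zmatrix_to_cartesian(z)
        assert np.linalg.norm(xyz[2] - xyz[1]) == pytest.approx(1.5, abs=1e-10)
        assert measure_angle(xyz[0], xyz[1], xyz[2]) == pytest.approx(90.0, abs=1e-8)
        assert abs(measure_dihedral(*xyz)) == pytest.approx(180.0, abs=1e-8)
        # dihedral 180 -> coplanar
        assert abs(np.linalg.det(np.vstack([xyz[1] - xyz[0], xyz[2] - xyz[0],
                                            xyz[3] - xyz[0]]))) < 1e-9

    def test_degenerate_angle_raises(self):
        z = ZMatrix(rows=[
            ZMatrixRow("C"),
            ZMatrixRow("C", 0, bond=1.5),
            ZMatrixRow("C", 1, 0, bond=1.5, angle=120.0),
            ZMatrixRow("C", 2, 1, 0, bond=1.5, angle=180.0, dihedral=0.0),
        ])
        with pytest.raises(DegenerateGeometryError):
            zmatrix_to_cartesian(z)


class TestCartesianToZMatrix:
    def test_water_bond_rows(self, water):
        z = cartesian_to_zmatrix(water)
        assert len(z.rows) == 3
        assert z.rows[1].bond == pytest.approx(0.96, abs=1e-9)

    def test_roundtrip_random_zmatrices(self, kabsch_rmsd):
        """cart -> zmat -> cart reproduces geometry to < 1e-8 A RMSD."""
        from mmkit.molsys import Atom, MolecularSystem, Residue
        rng = np.random.default_rng(7)
        for _ in range(10):
            z = ZMatrix()
            n = int(rng.integers(4, 30))
            for k in range(n):
                row = ZMatrixRow("C")
                if k >= 1:
                    row.bond_ref = k - 1
                    row.bond = float(rng.uniform(1.0, 1.8))
                if k >= 2:
                    row.angle_ref = k - 2
                    row.angle = float(rng.uniform(15.0, 165.0))
                if k >= 3:
                    row.dihedral_ref = k - 3
                    row.dihedral = float(rng.uniform(-180.0, 180.0))
                z.rows.append(row)
            xyz = zmatrix_to_cartesian(z)
            s = MolecularSystem()
            s.residues.append(Residue("MOL", "A", 1, kind="ligand"))
            for k, p in enumerate(xyz):
                s.atoms.append(Atom(k + 1, "C", "C", p, residue_index=0))
                s.residues[0].atom_indices.append(k)
            for i in range(n - 1):
                s.add_bond(i, i + 1)
            xyz2 = zmatrix_to_cartesian(cartesian_to_zmatrix(s))
            assert kabsch_rmsd(xyz, xyz2) < 1e-8

    def test_roundtrip_peptide(self, polyala3, kabsch_rmsd):
        z = cartesian_to_zmatrix(polyala3)
        xyz2 = zmatrix_to_cartesian(z)
        assert kabsch_rmsd(polyala3.coords(), xyz2) < 1e-8

    def test_linear_triatomic_flagged(self):
        s = read_xyz("3\n\nC 0 0 0\nC 1.2 0 0\nC 2.4 0 0\n")
        with pytest.raises(DegenerateGeometryError):
            cartesian_to_zmatrix(s)

    def test_text_roundtrip(self, polyala3):
        z = cartesian_to_zmatrix(polyala3)
        z2 = read_zmatrix_text(write_zmatrix_text(z))
        for r1, r2 in zip(z.rows, z2.rows):
            assert r1.bond_ref == r2.bond_ref
            assert r1.bond == pytest.approx(r2.bond, abs=1e-6)
            assert r1.dihedral == pytest.approx(r2.dihedral, abs=1e-6)


class TestSetTorsion:
    def test_sweep_hits_requested_values(self, butane):
        for value in range(-180, 181, 30):
            set_torsion(butane, (0, 1, 2, 3), float(value))
            got = measure_dihedral(*(butane.atoms[i].pos for i in range(4)))
            assert ((got - value + 180) % 360) - 180 == pytest.approx(0.0, abs=1e-6)

    def test_identity_leaves_coordinates(self, butane):
        before = butane.coords()
        cur = measure_dihedral(*(butane.atoms[i].pos for i in range(4)))
        set_torsion(butane, (0, 1, 2, 3), cur)
        assert np.abs(butane.coords() - before).max() < 1e-12

    def test_bond_lengths_preserved(self, butane):
        ref = {b: np.linalg.norm(butane.atoms[b[0]].pos - butane.atoms[b[1]].pos)
               for b in butane.bonds}
        set_torsion(butane, (0, 1, 2, 3), 73.0)
        for b, r in ref.items():
            assert np.linalg.norm(butane.atoms[b[0]].pos - butane.atoms[b[1]].pos) \
                == pytest.approx(r, abs=1e-9)

    def test_rigid_component_isometry(self, polyala3):
        """All pairwise distances within each side of the rotated bond are
        unchanged."""
        import copy
        s = copy.deepcopy(polyala3)
        quads = backbone_torsions(s)
        # rotate psi of residue 0
        names = {s.atoms[i].name: i for i in s.residues[0].atom_indices}
        n_next = next(i for i in s.residues[1].atom_indices if s.atoms[i].name == "N")
        quad = (names["N"], names["CA"], names["C"], n_next)
        from mmkit.internal_coords import _split_by_bond
        side_j, side_k = _split_by_bond(s, quad[1], quad[2])
        before = s.coords()
        set_torsion(s, quad, 77.0)
        after = s.coords()
        for side in (sorted(side_j), sorted(side_k)):
            d0 = np.linalg.norm(before[side][:, None] - before[side][None], axis=-1)
            d1 = np.linalg.norm(after[side][:, None] - after[side][None], axis=-1)
            assert np.abs(d0 - d1).max() < 1e-9

    def test_only_smaller_component_moves(self, polyala3):
        import copy
        s = copy.deepcopy(polyala3)
        names = {s.atoms[i].name: i for i in s.residues[0].atom_indices}
        n_next = next(i for i in s.residues[1].atom_indices if s.atoms[i].name == "N")
        quad = (names["N"], names["CA"], names["C"], n_next)
        from mmkit.internal_coords import _split_by_bond
        side_j, side_k = _split_by_bond(s, quad[1], quad[2])
        smaller = side_j if len(side_j) < len(side_k) else side_k
        larger = side_k if smaller is side_j else side_j
        before = s.coords()
        set_torsion(s, quad, 77.0)
        assert np.abs(s.coords()[sorted(larger)] - before[sorted(larger)]).max() < 1e-12

    def test_ring_bond_raises(self):
        pts = [f"C {1.5 * math.cos(math.radians(60 * k)):.4f} "
               f"{1.5 * math.sin(math.radians(60 * k)):.4f} {0.2 * (-1) ** k:.4f}"
               for k in range(6)]
        ring = read_xyz("6\n\n" + "\n".join(pts) + "\n")
        with pytest.raises(RingTorsionError):
            set_torsion(ring, (0, 1, 2, 3), 60.0)


class TestMutation:
    def test_ala_to_gly_removes_side_chain(self):
        s = make_polyala(3)
        mutate_residue(s, 1, "GLY")
        names = {s.atoms[i].name for i in s.residues[1].atom_indices}
        assert "CB" not in names
        assert {"N", "CA", "C", "O"} <= names

    def test_backbone_unmoved_and_restored(self):
        s = make_polyala(3)
        ref = {s.atoms[i].name: s.atoms[i].pos.copy()
               for i in s.residues[1].atom_indices
               if s.atoms[i].name in ("N", "CA", "C", "O")}
        mutate_residue(s, 1, "GLY")
        mutate_residue(s, 1, "ALA")
        for nm, p in ref.items():
            i = next(k for k in s.residues[1].atom_indices if s.atoms[k].name == nm)
            assert np.abs(s.atoms[i].pos - p).max() < 1e-12

    def test_ala_to_phe_chi_matches_first_rotamer(self):
        s = make_polyala(3)
        mutate_residue(s, 1, "PHE")
        chi = measure_chi(s, 1)
        assert chi[0] == pytest.approx(-60.0, abs=1e-6)
        assert chi[1] == pytest.approx(-60.0, abs=1e-6)

    @pytest.mark.parametrize("name,natoms_heavy", [
        ("SER", 6), ("LYS", 9), ("TRP", 14), ("HIS", 10), ("ARG", 11)])
    def test_template_atom_sets(self, name, natoms_heavy):
        s = make_polyala(3)
        mutate_residue(s, 1, name)
        heavy = [i for i in s.residues[1].atom_indices if s.atoms[i].element != "H"]
        assert len(heavy) == natoms_heavy
        # bonds connect the new side chain
        adj = s.neighbours()
        for i in heavy:
            assert adj[i], f"atom {s.atoms[i].name} left unbonded"

    def test_unknown_code_raises(self):
        s = make_polyala(2)
        with pytest.raises(ValueError):
            mutate_residue(s, 0, "XXX")


class TestRamachandran:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-60.0, -45.0, "favoured"),
        (0.0, 0.0, "outlier"),
        (-120.0, 130.0, "favoured"),
        (60.0, 40.0, "allowed"),
        (150.0, -150.0, "outlier"),
    ])
    def test_classification(self, phi, psi, expected):
        assert classify_ramachandran(phi, psi) == expected

    def test_piecewise_constant_under_small_perturbation(self):
        for phi, psi in [(-60, -45), (0, 0), (-120, 130)]:
            base = classify_ramachandran(phi, psi)
            assert classify_ramachandran(phi + 0.01, psi - 0.01) == base

    def test_helix_fixture_is_favoured(self, polyala3):
        t = backbone_torsions(polyala3)[1]
        assert classify_ramachandran(t["phi"], t["psi"]) == "favoured"
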