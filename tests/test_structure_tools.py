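"""Rotamers, hydrogen placement, polar-hydrogen optimisation, surfaces."""

import copy
import math

import numpy as np
import pytest

from mmkit.data import CHI_COUNTS
from mmkit.fixtures import make_polyala, make_toy_paramset
from mmkit.internal_coords import measure_chi, measure_dihedral, mutate_residue
from mmkit.molsys import (VDW_RADII, measure_angle, perceive_topology,
                          read_xyz)
from mmkit.scoring import DistanceHistogram, pmf_from_histogram, type_by_element
from mmkit.structure_tools import (FlipDecision, RotamerLibrary,
                                   RotamerScanOptions, apply_rotamer,
                                   enumerate_rotamers,
                                   optimize_polar_hydrogens,
                                   place_missing_hydrogens, polar_surface_area,
                                   rotamer_scan, sasa)


class TestEnumerateRotamers:
    @pytest.mark.parametrize("name,count", [("GLY", 1), ("ALA", 1), ("PRO", 1),
                                            ("SER", 3), ("VAL", 3), ("LEU", 9),
                                            ("PHE", 9), ("MET", 27), ("GLN", 27),
                                            ("LYS", 81), ("ARG", 81)])
    def test_three_state_counts(self, name, count):
        assert len(enumerate_rotamers(name)) == count

    def test_count_is_three_to_the_chi_for_all_residues(self):
        for name, nchi in CHI_COUNTS.items():
            assert len(enumerate_rotamers(name)) == 3 ** nchi

    def test_unknown_residue_raises(self):
        with pytest.raises(KeyError):
            enumerate_rotamers("XYZ")

    def test_file_library_roundtrip(self):
        text = "SER -65.2\nSER 62.1\nLEU -60 175\n# comment\n"
        lib = RotamerLibrary.from_text(text)
        assert lib.rotamers("SER") == [(-65.2,), (62.1,)]
        assert lib.rotamers("LEU") == [(-60.0, 175.0)]

    def test_file_library_chi_count_checked(self):
        with pytest.raises(ValueError, match="chi"):
            RotamerLibrary.from_text("SER -60 70\n")


class TestApplyRotamer:
    def test_empty_tuple_is_identity(self):
        s = make_polyala(3)
        before = s.coords()
        apply_rotamer(s, 1, ())
        assert np.abs(s.coords() - before).max() == 0.0

    def test_ser_chi1(self):
        s = make_polyala(3)
        mutate_residue(s, 1, "SER")
        apply_rotamer(s, 1, (180.0,))
        assert measure_chi(s, 1)[0] == pytest.approx(180.0, abs=1e-6)

    def test_lys_all_four_chis(self):
        s = make_polyala(3)
        mutate_residue(s, 1, "LYS")
        target = (60.0, 180.0, -60.0, 180.0)
        apply_rotamer(s, 1, target)
        got = measure_chi(s, 1)
        for t, g in zip(target, got):
            assert g == pytest.approx(t, abs=1e-6)

    def test_backbone_unmoved(self):
        s = make_polyala(3)
        mutate_residue(s, 1, "MET")
        bb = {i: s.atoms[i].pos.copy() for i in s.residues[1].atom_indices
              if s.atoms[i].name in ("N", "CA", "C", "O")}
        apply_rotamer(s, 1, (60.0, 60.0, 60.0))
        for i, p in bb.items():
            assert np.abs(s.atoms[i].pos - p).max() < 1e-12


def demo_tables(system):
    rng = np.random.default_rng(0)
    types = sorted(set(type_by_element(system)))
    tables = {}
    for t1 in types:
        for t2 in types:
            if (t2, t1) in tables:
                continue
            hist = DistanceHistogram((t1, t2), np.linspace(0.2, 12.0, 60),
                                     rng.uniform(0.5, 2.0, 59))
            tables[(t1, t2)] = pmf_from_histogram(hist, distance_scaled_exponent=1.61)
    return tables


class TestRotamerScan:
    def test_single_ala_trivially_ranked(self):
        s = make_polyala(3)
        result = rotamer_scan(s, RotamerScanOptions(residues=[1]),
                              tables=demo_tables(s))
        assert len(result.ranked) == 1

    def test_two_ser_nine_combinations_top_ten(self):
        s = make_polyala(4)
        mutate_residue(s, 1, "SER")
        mutate_residue(s, 2, "SER")
        result = rotamer_scan(s, RotamerScanOptions(residues=[1, 2]),
                              tables=demo_tables(s))
        assert len(result.ranked) == 9   # 3^2 combos, all kept (< top_k)
        scores = [r[1] for r in result.ranked]
        assert scores == sorted(scores)

    def test_matches_bruteforce_ranking(self):
        """Scan equals independent enumerate-score-sort on a two-residue
        pocket (<= 81 combos)."""
        s = make_polyala(4)
        mutate_residue(s, 1, "SER")
        mutate_residue(s, 2, "CYS")
        tables = demo_tables(s)
        opts = RotamerScanOptions(residues=[1, 2], top_k=10)
        result = rotamer_scan(s, opts, tables=tables)

        from itertools import product
        from mmkit.scoring import score_pose
        work = copy.deepcopy(s)
        lib = RotamerLibrary.three_state()
        scan_atoms = (work.residues[1].atom_indices + work.residues[2].atom_indices)
        env = [i for i in range(len(work.atoms)) if i not in set(scan_atoms)]
        brute = []
        for c1, c2 in product(lib.rotamers("SER"), lib.rotamers("CYS")):
            apply_rotamer(work, 1, c1)
            apply_rotamer(work, 2, c2)
            xyz = work.coords()
            tps = type_by_element(work)
            sc = score_pose(xyz[env], [tps[i] for i in env],
                            xyz[scan_atoms], [tps[i] for i in scan_atoms],
                            tables).total
            ia = work.residues[1].atom_indices
            ib = work.residues[2].atom_indices
            sc += score_pose(xyz[ia], [tps[i] for i in ia],
                             xyz[ib], [tps[i] for i in ib], tables).total
            brute.append(((c1, c2), sc))
        brute.sort(key=lambda t: t[1])
        assert len(result.ranked) == 9
        for (combo_a, score_a, _), (combo_b, score_b) in zip(result.ranked, brute):
            assert combo_a == combo_b
            assert score_a == pytest.approx(score_b, abs=1e-9)

    def test_top_k_retention(self):
        s = make_polyala(3)
        mutate_residue(s, 1, "MET")   # 27 combos
        result = rotamer_scan(s, RotamerScanOptions(residues=[1], top_k=10),
                              tables=demo_tables(s))
        assert len(result.ranked) == 10

    def test_residue_limit_enforced(self):
        with pytest.raises(ValueError):
            RotamerScanOptions(residues=[0, 1, 2, 3, 4, 5, 6])

    def test_combination_guard(self):
        s = make_polyala(8)
        for r in range(1, 7):
            mutate_residue(s, r, "LYS")
        opts = RotamerScanOptions(residues=[1, 2, 3, 4, 5, 6],
                                  max_combinations=1000)
        with pytest.raises(ValueError, match=r"\d+ combinations"):
            rotamer_scan(s, opts, tables=demo_tables(s))

    def test_forcefield_rescore_appended_without_reordering(self, toy_params):
        s = make_polyala(3)
        mutate_residue(s, 1, "SER")
        place_missing_hydrogens(s, residues=[1])
        tables = demo_tables(s)
        opts_plain = RotamerScanOptions(residues=[1], scorer="dfire")
        opts_resc = RotamerScanOptions(residues=[1], scorer="dfire", rescore=True)
        plain = rotamer_scan(s, opts_plain, tables=tables)
        resc = rotamer_scan(s, opts_resc, tables=tables, params=toy_params)
        assert [r[0] for r in resc.ranked] == [r[0] for r in plain.ranked]
        assert all(r[2] is not None for r in resc.ranked)


class TestHydrogenPlacement:
    def test_methane_tetrahedral(self):
        m = read_xyz("1\n\nC 0 0 0\n")
        place_missing_hydrogens(m)
        hs = [a for a in m.atoms if a.element == "H"]
        assert len(hs) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                ang = measure_angle(hs[i].pos, m.atoms[0].pos, hs[j].pos)
                assert ang == pytest.approx(109.471, abs=0.01)
            assert np.linalg.norm(hs[i].pos - m.atoms[0].pos) == pytest.approx(1.09, abs=1e-6)

    def test_benzene_in_plane(self):
        rows = [f"C {1.39 * math.cos(math.radians(60 * k)):.4f} "
                f"{1.39 * math.sin(math.radians(60 * k)):.4f} 0.0" for k in range(6)]
        b = read_xyz("6\n\n" + "\n".join(rows) + "\n")
        place_missing_hydrogens(b)
        hs = [a for a in b.atoms if a.element == "H"]
        assert len(hs) == 6
        for h in hs:
            assert abs(h.pos[2]) < 1e-9   # ring plane is z = 0
            # C-H points radially outward
            assert np.linalg.norm(h.pos[:2]) > 1.39

    def test_bare_water_oxygen(self):
        w = read_xyz("1\n\nO 0 0 0\n")
        place_missing_hydrogens(w)
        assert sum(1 for a in w.atoms if a.element == "H") == 2
        hs = [a.pos for a in w.atoms if a.element == "H"]
        assert measure_angle(hs[0], w.atoms[0].pos, hs[1]) == pytest.approx(104.5, abs=0.1)

    def test_stripped_peptide_restored_to_template_counts(self):
        s = make_polyala(4)
        expected = len(s.atoms)
        # strip all hydrogens
        from mmkit.internal_coords import _remove_atoms
        _remove_atoms(s, [i for i, a in enumerate(s.atoms) if a.element == "H"])
        place_missing_hydrogens(s)
        assert len(s.atoms) == expected

    def test_carbonyl_oxygen_gets_no_hydrogen(self):
        # formaldehyde-like: C=O at 1.22 A plus two H already present
        m = read_xyz("2\n\nC 0 0 0\nO 1.22 0 0\n")
        place_missing_hydrogens(m)
        names = [(a.element, a.residue_index) for a in m.atoms]
        assert sum(1 for e, _ in names if e == "H") == 2  # sp2 CH2, none on O
        adj = m.neighbours()
        assert not any(m.atoms[j].element == "H" for j in adj[1])


class TestPolarHydrogenOptimisation:
    def _prep(self, names):
        s = make_polyala(len(names) + 2)
        for k, nm in enumerate(names, start=1):
            mutate_residue(s, k, nm)
        place_missing_hydrogens(s)
        from mmkit.forcefield import assign_atom_types, assign_simple_charges
        assign_atom_types(s)
        assign_simple_charges(s)
        return s

    def test_isolated_ser_reported_degenerate_or_kept(self, toy_params):
        s = self._prep(["SER"])
        top = perceive_topology(s)
        _, decisions = optimize_polar_hydrogens(s, top, toy_params)
        assert any(isinstance(d, FlipDecision) for d in decisions)

    def test_hydroxyl_turns_toward_acceptor(self, toy_params):
        """A charged acceptor placed near a serine OH pulls the hydrogen
        toward it."""
        s = self._prep(["SER"])
        og = next(i for i in s.residues[1].atom_indices if s.atoms[i].name == "OG")
        adj = s.neighbours()
        hg = next(j for j in adj[og] if s.atoms[j].element == "H")
        # rotate the hydroxyl away, then add an acceptor 2.8 A from OG
        from mmkit.data import ROTATABLE_HYDROXYLS
        cb = next(i for i in s.residues[1].atom_indices if s.atoms[i].name == "CB")
        ca = next(i for i in s.residues[1].atom_indices if s.atoms[i].name == "CA")
        from mmkit.internal_coords import set_torsion
        from mmkit.molsys import Atom, Residue
        # put the acceptor straight along the O-H direction of one torsion
        # (so that torsion is the unique hydrogen-bonded orientation), then
        # rotate the hydroxyl away before optimising
        set_torsion(s, (ca, cb, og, hg), 180.0)
        oh = s.atoms[hg].pos - s.atoms[og].pos
        oh /= np.linalg.norm(oh)
        acceptor_pos = s.atoms[og].pos + 2.8 * oh
        set_torsion(s, (ca, cb, og, hg), 60.0)
        ridx = len(s.residues)
        s.residues.append(Residue(name="ACC", chain="B", seqnum=99, kind="ligand"))
        s.atoms.append(Atom(serial=999, name="O", element="O", pos=acceptor_pos,
                            charge=-0.8, residue_index=ridx))
        s.residues[ridx].atom_indices.append(len(s.atoms) - 1)
        s.default_charge_groups()
        top = perceive_topology(s)
        optimize_polar_hydrogens(s, top, toy_params)
        ang = measure_angle(s.atoms[og].pos, s.atoms[hg].pos, acceptor_pos)
        # O-H...A angle measured at H must be roughly linear
        assert measure_angle(acceptor_pos, s.atoms[hg].pos, s.atoms[og].pos) > 150.0

    def test_flip_is_involutive(self, toy_params):
        s = self._prep(["GLN"])
        from mmkit.data import FLIPPABLE
        byname = {s.atoms[i].name: i for i in s.residues[1].atom_indices}
        quad = tuple(byname[nm] for nm in FLIPPABLE["GLN"])
        from mmkit.internal_coords import set_torsion
        before = s.coords()
        cur = measure_dihedral(*(s.atoms[i].pos for i in quad))
        set_torsion(s, quad, cur + 180.0)
        set_torsion(s, quad, cur)
        assert np.abs(s.coords() - before).max() < 1e-9


class TestSurfaceAreas:
    def test_isolated_sphere_closed_form(self):
        s = read_xyz("1\n\nC 0 0 0\n")
        area = sasa(s, probe=1.4, n_points=960).sum()
        exact = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_full_overlap_counts_once(self):
        s = read_xyz("2\n\nC 0 0 0\nC 0.001 0 0\n")
        s.bonds = set()
        total = sasa(s, n_points=960).sum()
        exact = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert abs(total - exact) / exact < 0.01

    def test_total_area_monotone_with_separation(self):
        exact = 2 * 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        prev = -1.0
        for r in (1.0, 2.5, 4.0, 5.5, 7.0):
            s = read_xyz(f"2\n\nC 0 0 0\nC {r} 0 0\n")
            s.bonds = set()
            total = sasa(s, n_points=480).sum()
            assert total >= prev - 1e-9
            prev = total
        assert prev == pytest.approx(exact, rel=0.01)   # fully separated

    def test_psa_methane_zero(self):
        m = read_xyz("1\n\nC 0 0 0\n")
        place_missing_hydrogens(m)
        assert polar_surface_area(m) == 0.0

    def test_psa_water_equals_total_sasa(self):
        w = read_xyz("3\n\nO 0 0 0\nH 0.96 0 0\nH -0.24 0.93 0\n")
        assert polar_surface_area(w) == pytest.approx(sasa(w).sum(), abs=1e-9)

    def test_psa_methanol_selection_mask(self):
        m = read_xyz("2\n\nC 0 0 0\nO 1.43 0 0\n")
        place_missing_hydrogens(m)
        areas = sasa(m)
        adj = m.neighbours()
        expected = 0.0
        for i, a in enumerate(m.atoms):
            if a.element == "O":
                expected += areas[i]
            elif a.element == "H" and any(m.atoms[j].element == "O" for j in adj[i]):
                expected += areas[i]
        assert polar_surface_area(m) == pytest.approx(expected, abs=1e-9)
        assert 0.0 < polar_surface_area(m) < areas.sum()

    def test_psa_invariant_under_rigid_transform(self):
        from scipy.spatial.transform import Rotation
        w = read_xyz("3\n\nO 0 0 0\nH 0.96 0 0\nH -0.24 0.93 0\n")
        p0 = polar_surface_area(w)
        R = Rotation.random(random_state=1).as_matrix()
        w.set_coords(w.coords() @ R.T + np.array([3.0, 1.0, -2.0]))
        # invariance is limited by the fixed sphere-point quadrature (~0.1%)
        assert polar_surface_area(w) == pytest.approx(p0, rel=5e-3)
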