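"""PMF inversion, pose scoring, rigid transforms, three-point alignment."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mmkit.dynamics import KB
from mmkit.fixtures import make_synthetic_histograms
from mmkit.scoring import (DistanceHistogram, align_three_point,
                           pmf_from_histogram, read_table, score_pose,
                           transform_pose, write_table)


def flat_hist(counts, lo=1.0, hi=5.0):
    counts = np.asarray(counts, float)
    return DistanceHistogram(("A", "B"), np.linspace(lo, hi, len(counts) + 1), counts)


class TestPMFInversion:
    def test_observed_equals_reference_gives_zero(self):
        t = pmf_from_histogram(flat_hist(np.ones(10)), reference=flat_hist(np.ones(10)))
        assert np.abs(t.energies).max() == 0.0

    def test_boltzmann_factor_arithmetic(self):
        """A bin whose occupancy is e^-1 of the reference lies kB*T above a
        bin matching the reference; with kB*T = 0.6 that difference is
        0.6 kcal/mol."""
        T = 0.6 / KB
        obs = flat_hist([math.exp(-1.0), 1.0])
        ref = flat_hist([1.0, 1.0])
        t = pmf_from_histogram(obs, reference=ref, T=T)
        assert t.energies[0] - t.energies[1] == pytest.approx(0.6, rel=1e-9)

    def test_cutoff_bin_anchored_at_zero(self):
        rng = np.random.default_rng(0)
        t = pmf_from_histogram(flat_hist(rng.uniform(0.5, 2.0, 12)),
                               distance_scaled_exponent=1.61)
        assert t.energies[-1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_bins_capped(self):
        counts = np.ones(8)
        counts[3] = 0.0
        t = pmf_from_histogram(flat_hist(counts), reference=flat_hist(np.ones(8)),
                               e_max=3.0)
        assert t.energies[3] == t.energies.max()
        assert t.energies[3] - t.energies[0] == pytest.approx(3.0, abs=0.2)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            pmf_from_histogram(flat_hist(np.ones(5)), reference=flat_hist(np.zeros(5)))

    def test_recovers_generating_potential(self):
        """Boltzmann sample of a two-well potential, histogrammed and
        inverted, reproduces the potential within sampling error."""
        def pot(r):
            return (-1.5 * math.exp(-((r - 3.0) ** 2) / 0.5)
                    - 0.8 * math.exp(-((r - 5.5) ** 2) / 0.5))
        obs, ref = make_synthetic_histograms(pot, n_samples=150000, seed=3)
        t = pmf_from_histogram(obs, reference=ref, T=300.0)
        c = t.centres
        true = np.array([pot(x) for x in c])
        true -= true[c < t.cutoff][-1]
        mask = (c > 2.0) & (c < 7.5)   # region with adequate counts
        assert np.abs(t.energies[mask] - true[mask]).max() < 0.15

    def test_error_shrinks_with_sample_size(self):
        def pot(r):
            return -1.2 * math.exp(-((r - 3.5) ** 2) / 0.6)
        errs = []
        for n in (4000, 64000):
            obs, ref = make_synthetic_histograms(pot, n_samples=n, seed=5)
            t = pmf_from_histogram(obs, reference=ref, T=300.0)
            c = t.centres
            true = np.array([pot(x) for x in c])
            true -= true[c < t.cutoff][-1]
            mask = (c > 2.2) & (c < 6.0)
            errs.append(float(np.sqrt(np.mean((t.energies[mask] - true[mask]) ** 2))))
        assert errs[1] < errs[0]

    def test_table_file_roundtrip(self):
        rng = np.random.default_rng(1)
        t = pmf_from_histogram(flat_hist(rng.uniform(0.5, 2.0, 20), 0.2, 12.0),
                               distance_scaled_exponent=1.61)
        t2 = read_table(write_table(t))
        assert t2.type_pair == t.type_pair
        assert t2.cutoff == pytest.approx(t.cutoff)
        assert np.abs(t2.energies - t.energies).max() < 1e-5
        assert t2.reference_mode == "distance_scaled"


def demo_table(seed=0, pair=("C", "O")):
    rng = np.random.default_rng(seed)
    hist = DistanceHistogram(pair, np.linspace(0.2, 12.0, 60),
                             rng.uniform(0.5, 2.0, 59))
    return pmf_from_histogram(hist, distance_scaled_exponent=1.61)


class TestScorePose:
    def test_single_pair_interpolated_lookup(self):
        t = demo_table()
        r = 4.37
        expected = t.interpolate(r)
        sc = score_pose(np.array([[0.0, 0, 0]]), ["C"],
                        np.array([[r, 0, 0]]), ["O"], {("C", "O"): t})
        assert sc.total == pytest.approx(expected, abs=1e-12)

    def test_beyond_cutoff_is_zero(self):
        t = demo_table()
        sc = score_pose(np.array([[0.0, 0, 0]]), ["C"],
                        np.array([[t.cutoff + 1.0, 0, 0]]), ["O"],
                        {("C", "O"): t})
        assert sc.total == 0.0
        assert sc.pair_contributions == []

    def test_matches_independent_bruteforce(self):
        """10 x 10 atom fixture against a separately coded double loop with
        its own interpolation."""
        t = demo_table(2)
        rng = np.random.default_rng(3)
        pxyz = rng.uniform(0, 8, (10, 3))
        lxyz = rng.uniform(0, 8, (10, 3))
        sc = score_pose(pxyz, ["C"] * 10, lxyz, ["O"] * 10, {("C", "O"): t})
        c = t.centres
        brute = 0.0
        for p in pxyz:
            for l in lxyz:
                r = float(np.linalg.norm(p - l))
                if r >= t.cutoff:
                    continue
                if r <= c[0]:
                    e = t.energies[0]
                elif r >= c[-1]:
                    e = t.energies[-1]
                else:
                    k = int(np.searchsorted(c, r)) - 1
                    w = (r - c[k]) / (c[k + 1] - c[k])
                    e = (1 - w) * t.energies[k] + w * t.energies[k + 1]
                brute += e
        assert sc.total == pytest.approx(brute, abs=1e-10)

    def test_decomposition_sums_to_total(self):
        t = demo_table(4)
        rng = np.random.default_rng(5)
        sc = score_pose(rng.uniform(0, 6, (6, 3)), ["C"] * 6,
                        rng.uniform(0, 6, (5, 3)), ["O"] * 5, {("C", "O"): t})
        assert sum(e for *_, e in sc.pair_contributions) == pytest.approx(
            sc.total, abs=1e-10)

    def test_invariant_under_joint_rigid_transform(self):
        t = demo_table(6)
        rng = np.random.default_rng(7)
        pxyz = rng.uniform(0, 6, (5, 3))
        lxyz = rng.uniform(0, 6, (4, 3))
        s0 = score_pose(pxyz, ["C"] * 5, lxyz, ["O"] * 4, {("C", "O"): t}).total
        R = Rotation.random(random_state=8).as_matrix()
        shift = np.array([3.0, -2.0, 7.0])
        s1 = score_pose(pxyz @ R.T + shift, ["C"] * 5, lxyz @ R.T + shift,
                        ["O"] * 4, {("C", "O"): t}).total
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_missing_pair_warns_and_scores_zero(self):
        t = demo_table()
        with pytest.warns(UserWarning, match="no pair potential"):
            sc = score_pose(np.array([[0.0, 0, 0]]), ["N"],
                            np.array([[3.0, 0, 0]]), ["O"], {("C", "O"): t})
        assert sc.total == 0.0
        with pytest.raises(KeyError):
            score_pose(np.array([[0.0, 0, 0]]), ["N"],
                       np.array([[3.0, 0, 0]]), ["O"], {("C", "O"): t},
                       default_zero=False)


class TestTransformPose:
    def test_identity(self):
        xyz = np.random.default_rng(0).uniform(-2, 2, (5, 3))
        out = transform_pose(xyz)
        assert np.abs(out - xyz).max() == 0.0

    def test_translation_inverse(self):
        xyz = np.random.default_rng(1).uniform(-2, 2, (5, 3))
        out = transform_pose(transform_pose(xyz, translation=(1, 0, 0)),
                             translation=(-1, 0, 0))
        assert np.abs(out - xyz).max() < 1e-12

    def test_rotation_preserves_internal_distances(self):
        xyz = np.random.default_rng(2).uniform(-2, 2, (8, 3))
        R = Rotation.random(random_state=3).as_matrix()
        out = transform_pose(xyz, rotation=R)
        d0 = np.linalg.norm(xyz[:, None] - xyz[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-12

    def test_improper_rotation_rejected(self):
        xyz = np.zeros((2, 3))
        mirror = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            transform_pose(xyz, rotation=mirror)


class TestThreePointAlignment:
    def test_identity_on_same_molecule(self):
        xyz = np.random.default_rng(4).uniform(-3, 3, (7, 3))
        out = align_three_point(xyz, xyz, (0, 1, 2), (0, 1, 2))
        assert np.abs(out - xyz).max() < 1e-10

    def test_recovers_rigid_copy_exactly(self):
        target = np.random.default_rng(5).uniform(-3, 3, (9, 3))
        R = Rotation.random(random_state=6).as_matrix()
        mobile = target @ R.T + np.array([4.0, -1.0, 2.0])
        out = align_three_point(mobile, target, (0, 1, 2), (0, 1, 2))
        assert np.sqrt(np.mean(np.sum((out - target) ** 2, axis=1))) < 1e-10

    def test_constraint_geometry_for_distinct_molecules(self):
        """Different molecules sharing a 3-atom motif: point 1 coincides, the
        1->2 direction matches, and point 3 lies in-plane on the same side."""
        rng = np.random.default_rng(7)
        target = rng.uniform(-3, 3, (6, 3))
        mobile = rng.uniform(-3, 3, (5, 3))
        tm, tt = (0, 1, 2), (1, 3, 4)
        out = align_three_point(mobile, target, tm, tt)
        p1t, p2t, p3t = (target[i] for i in tt)
        assert np.linalg.norm(out[tm[0]] - p1t) < 1e-10
        v_m = out[tm[1]] - out[tm[0]]
        v_t = p2t - p1t
        cosang = np.dot(v_m, v_t) / (np.linalg.norm(v_m) * np.linalg.norm(v_t))
        assert cosang == pytest.approx(1.0, abs=1e-12)
        normal = np.cross(v_t, p3t - p1t)
        assert abs(np.dot(out[tm[2]] - p1t, normal)) < 1e-9          # in plane
        side_m = np.dot(np.cross(v_t, out[tm[2]] - p1t), normal)
        assert side_m > 0                                             # same side
        # rigid: internal distances preserved
        d0 = np.linalg.norm(mobile[:, None] - mobile[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        target = rng.uniform(-3, 3, (5, 3))
        mobile = rng.uniform(-3, 3, (5, 3))
        once = align_three_point(mobile, target, (0, 1, 2), (0, 1, 2))
        twice = align_three_point(once, target, (0, 1, 2), (0, 1, 2))
        assert np.abs(twice - once).max() < 1e-10

    def test_collinear_triplet_rejected(self):
        bad = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [1.0, 1, 0]])
        good = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [1.0, 1, 0]])
        with pytest.raises(ValueError, match="collinear"):
            align_three_point(bad, good, (0, 1, 2), (0, 1, 2))
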