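"""Structural statistics: oracles, hand cases, rigid invariance."""

import numpy as np
import pytest

from bbdiff import (assign_secondary_structure, contact_density, contact_order,
                    kabsch_rmsd, long_range_contact_fraction, make_ideal_helix,
                    make_ideal_strand, make_random_coil, make_synthetic_set,
                    radius_of_gyration, ss_fractions, structure_stats)
from bbdiff.geometry import apply_rigid, random_rigid_motion


class TestRadiusOfGyration:
    def test_two_points_two_angstrom_apart(self):
        assert np.isclose(radius_of_gyration(np.array([[0.0, 0, 0], [2, 0, 0]])), 1.0)

    def test_coincident_points(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_matches_brute_force(self):
        ca = make_synthetic_set(1, (50, 50), seed=1)[0].ca
        brute = np.sqrt(np.mean([np.sum((p - ca.mean(0)) ** 2) for p in ca]))
        assert abs(radius_of_gyration(ca) - brute) < 1e-10


class TestContactOrder:
    def test_no_contacts_gives_zero(self):
        ca = np.arange(10)[:, None] * np.array([20.0, 0, 0])
        assert contact_order(ca) == 0.0

    def test_three_residue_hand_case(self):
        # single contact (0, 2) at separation 2 with L=3: RCO = 2 / (3*1)
        ca = np.array([[0.0, 0, 0], [20.0, 0, 0], [3.0, 0, 0]])
        assert np.isclose(contact_order(ca, cutoff=8.0, min_separation=2), 2 / 3)

    def test_matches_brute_force_double_loop(self):
        ca = make_synthetic_set(1, (100, 100), seed=3)[0].ca
        n = len(ca)
        total, count = 0, 0
        for i in range(n):
            for j in range(i + 3, n):
                if np.linalg.norm(ca[i] - ca[j]) <= 8.0:
                    total += j - i
                    count += 1
        expected = total / (n * count) if count else 0.0
        assert abs(contact_order(ca) - expected) < 1e-12
        assert abs(contact_density(ca) - count / n) < 1e-12


class TestSecondaryStructure:
    def test_helix_assigned_helical(self):
        h, _, _ = ss_fractions(make_ideal_helix(40))
        assert h >= 0.9

    def test_strand_assigned_extended(self):
        _, e, _ = ss_fractions(make_ideal_strand(40))
        assert e >= 0.8

    @pytest.mark.parametrize("seed", range(5))
    def test_coil_mostly_unassigned(self, seed):
        h, e, _ = ss_fractions(make_random_coil(40, seed=seed))
        assert h + e < 0.2

    def test_short_chain_all_coil(self):
        labels = assign_secondary_structure(make_ideal_helix(4))
        assert np.all(labels == "C")


class TestKabschRMSD:
    def test_identical_sets(self):
        a = np.random.default_rng(0).standard_normal((10, 3))
        assert kabsch_rmsd(a, a) < 1e-12

    def test_rigidly_moved_copy(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((20, 3))
        rot, trans = random_rigid_motion(rng)
        assert kabsch_rmsd(a, apply_rigid(a, rot, trans)) < 1e-8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_three_point_case_matches_rotation_grid_search(self):
        from scipy.spatial.transform import Rotation

        a = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.0, 4.0, 0]])
        b = np.array([[0.2, 0, 0], [2.9, 0.3, 0], [2.7, 4.1, 0.4]])
        ac, bc = a - a.mean(0), b - b.mean(0)

        def grid_min(center, half_width, steps):
            angles = [np.linspace(c - half_width, c + half_width, steps)
                      for c in center]
            best, best_euler = np.inf, center
            for e1 in angles[0]:
                for e2 in angles[1]:
                    for e3 in angles[2]:
                        rot = Rotation.from_euler("zyz", [e1, e2, e3]).as_matrix()
                        rmsd = np.sqrt(((bc @ rot.T - ac) ** 2).sum(1).mean())
                        if rmsd < best:
                            best, best_euler = rmsd, (e1, e2, e3)
            return best, best_euler

        # coarse scan of SO(3), then direct simplex descent from the argmin —
        # an oracle that never touches the SVD closed form
        from scipy.optimize import minimize

        best, euler = grid_min((np.pi, np.pi / 2, np.pi), np.pi, 25)

        def rmsd_of(euler_angles):
            rot = Rotation.from_euler("zyz", euler_angles).as_matrix()
            return np.sqrt(((bc @ rot.T - ac) ** 2).sum(1).mean())

        res = minimize(rmsd_of, euler, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        assert abs(kabsch_rmsd(a, b) - res.fun) < 1e-3


class TestInvariance:
    def test_all_metrics_rigid_invariant(self):
        s = make_synthetic_set(1, (60, 60), seed=4)[0]
        rng = np.random.default_rng(5)
        rot, trans = random_rigid_motion(rng)
        moved = apply_rigid(s.ca, rot, trans)
        assert abs(radius_of_gyration(s.ca) - radius_of_gyration(moved)) < 1e-8
        assert abs(contact_order(s.ca) - contact_order(moved)) < 1e-8
        assert abs(long_range_contact_fraction(s.ca)
                   - long_range_contact_fraction(moved)) < 1e-8
        assert np.array_equal(assign_secondary_structure(s.ca),
                              assign_secondary_structure(moved))


def test_structure_stats_record_is_consistent():
    s = make_synthetic_set(1, (80, 80), seed=6)[0]
    stats = structure_stats(s)
    assert stats.n_residues == 80
    assert 0 <= stats.relative_contact_order <= 1
    assert np.isclose(stats.helix_fraction + stats.strand_fraction
                      + stats.coil_fraction, 1.0)
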