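"""Superposition, RMSD matrices, dihedrals, residue distances."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allotrace.geometry import (
    dihedral, kabsch_superpose, min_residue_distance, rmsd_matrix_2d, rmsd_series,
)
from allotrace.structure_io import AtomRecord, Structure, Trajectory
from conftest import random_rotation


def quaternion_oracle_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Brute-force minimum RMSD over rotations (multi-start quaternion refine).

    Independent of the SVD path: parameterises rotations by rotation
    vectors, evaluates the raw objective, and polishes the best grid point.
    """
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((x @ r.T - y) ** 2, axis=1)))

    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(40):
        rv0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return float(best)


class TestKabsch:
    def test_identity_on_self(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd < 1e-10
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_recovers_planted_rigid_motion(self, rng):
        pts = rng.normal(size=(12, 3)) * 5
        rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -2.0, 1.0])
        res = kabsch_superpose(moved, pts)
        assert res.rmsd < 1e-6
        assert np.allclose(res.rotation @ rot, np.eye(3), atol=1e-6)
        assert np.allclose(res.apply(moved), pts, atol=1e-6)

    def test_rotation_is_proper(self, rng):
        for _ in range(5):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            res = kabsch_superpose(a, b)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        pts = rng.normal(size=(10, 3)) * 4
        noisy = pts @ random_rotation(rng).T + rng.normal(scale=0.3, size=(10, 3)) + 2.0
        ours = kabsch_superpose(noisy, pts).rmsd
        oracle = quaternion_oracle_rmsd(noisy, pts)
        assert ours == pytest.approx(oracle, abs=1e-5)
        assert ours <= oracle + 1e-9  # Kabsch is the global optimum

    def test_count_mismatch_and_too_few_points(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestRmsdSeries:
    def test_identical_frames_zero(self, tripeptide):
        traj = Trajectory(tripeptide, np.stack([tripeptide.coordinates] * 4))
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-10)

    def test_uniform_translation_removed(self, tripeptide):
        c = tripeptide.coordinates
        traj = Trajectory(tripeptide, np.stack([c, c + np.array([1.0, 0, 0])]))
        assert rmsd_series(traj)[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_per_frame_superposition(self, two_state_traj):
        traj, _ = two_state_traj
        sub = traj.slice_frames(0, 10)
        series = rmsd_series(sub, 0, "backbone")
        from allotrace.structure_io import resolve_selection
        idx = resolve_selection(sub.topology, "backbone").indices
        for f in range(sub.n_frames):
            expected = kabsch_superpose(sub.frames[f][idx], sub.frames[0][idx]).rmsd
            assert series[f] == pytest.approx(expected, abs=1e-12)


class TestRmsdMatrix:
    def test_self_matrix_symmetric_zero_diagonal(self, two_state_traj):
        traj, _ = two_state_traj
        sub = traj.slice_frames(0, 5)
        mat = rmsd_matrix_2d(sub, sub, "calpha")
        assert np.allclose(mat.values, mat.values.T, atol=1e-12)
        assert np.allclose(np.diag(mat.values), 0.0)

    def test_rigidly_moved_single_frame_is_zero(self, tripeptide, rng):
        c = tripeptide.coordinates
        a = Trajectory(tripeptide, c[None])
        moved = c @ random_rotation(rng).T + np.array([3.0, 1.0, -2.0])
        b = Trajectory(tripeptide, moved[None])
        mat = rmsd_matrix_2d(a, b)
        assert mat.values.shape == (1, 1)
        assert mat.values[0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_cross_matrix_equals_elementwise_kabsch(self, two_state_traj):
        traj, _ = two_state_traj
        a, b = traj.slice_frames(0, 5), traj.slice_frames(10, 14)
        from allotrace.structure_io import resolve_selection
        idx = resolve_selection(traj.topology, "calpha").indices
        mat = rmsd_matrix_2d(a, b, "calpha")
        for i in range(5):
            for j in range(4):
                expected = kabsch_superpose(a.frames[i][idx], b.frames[j][idx]).rmsd
                assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_nm_conversion(self, two_state_traj):
        traj, _ = two_state_traj
        sub = traj.slice_frames(0, 3)
        mat = rmsd_matrix_2d(sub, sub, "backbone")
        assert np.allclose(mat.values_nm, mat.values / 10.0)


def oracle_dihedral(p1, p2, p3, p4) -> float:
    """Independent torsion via plane normals and atan2 on a constructed frame."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = [np.array([1.0, 1.0, 0]), np.array([1.0, 0.0, 0]),
             np.array([0.0, 0.0, 0]), np.array([0.0, 1.0, 0])]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        p = [np.array([1.0, 1.0, 0]), np.array([1.0, 0.0, 0]),
             np.array([0.0, 0.0, 0]), np.array([0.0, -1.0, 0])]
        assert abs(dihedral(*p)) == pytest.approx(180.0, abs=1e-10)

    def test_matches_independent_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except ValueError:
                continue
            assert ours == pytest.approx(oracle_dihedral(*pts), abs=1e-8)

    def test_reversal_preserves_sign(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                fwd = dihedral(*pts)
            except ValueError:
                continue
            assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-10)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            dihedral(np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]),
                     np.array([3.0, 1.0, 0]))


class TestMinResidueDistance:
    @staticmethod
    def _two_atom_structure():
        return Structure([
            AtomRecord(1, "NZ", "LYS", 1, "A", np.zeros(3), "N"),
            AtomRecord(2, "OE1", "GLU", 2, "A", np.array([3.0, 4.0, 0.0]), "O"),
        ])

    def test_three_four_five(self):
        s = self._two_atom_structure()
        assert min_residue_distance(s.coordinates, s, 1, 2) == pytest.approx(5.0)

    def test_self_distance_zero(self):
        s = self._two_atom_structure()
        assert min_residue_distance(s.coordinates, s, 1, 1) == 0.0

    def test_matches_all_pairs_brute_force(self, single_state_traj):
        traj, _ = single_state_traj
        top = traj.topology
        frame = traj.frames[0]
        ia = [i for i in top.residue_atom_indices(521)]
        ib = [i for i in top.residue_atom_indices(1364)]
        brute = min(np.linalg.norm(frame[i] - frame[j]) for i in ia for j in ib)
        assert min_residue_distance(frame, top, 521, 1364, "all") == pytest.approx(brute)

    def test_absent_residue_rejected(self, tripeptide):
        with pytest.raises(ValueError, match="not found"):
            min_residue_distance(tripeptide.coordinates, tripeptide, 1, 99)
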