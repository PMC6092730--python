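import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from endoguide.geometry import (
    CorrespondenceError,
    DegenerateConfigurationError,
    FiducialSet,
    Frame,
    RegistrationResult,
    RigidTransform,
    apply_transform,
    match_correspondence,
    random_rigid_transform,
    register_rigid,
    target_registration_error,
)


def _fidset(points, frame=Frame.CT, prefix="p"):
    points = np.asarray(points, dtype=float)
    return FiducialSet(points, [f"{prefix}{i}" for i in range(len(points))], frame)


TETRA = np.array(
    [[0.0, 0.0, 0.0], [50.0, 0.0, 0.0], [0.0, 40.0, 0.0], [10.0, 10.0, 30.0]]
)


class TestRigidTransform:
    def test_identity_apply(self):
        assert np.allclose(
            apply_transform(RigidTransform.identity(), [(1.0, 2.0, 3.0)]), [(1, 2, 3)]
        )

    def test_pure_translation(self):
        t = RigidTransform(np.eye(3), [1.0, 2.0, 3.0])
        assert np.allclose(t.apply([0.0, 0.0, 0.0]), [1, 2, 3])

    def test_rot90_about_z(self):
        t = RigidTransform.from_axis_angle([0, 0, 1], np.pi / 2)
        assert np.allclose(t.apply([1.0, 0.0, 0.0]), [0, 1, 0], atol=1e-12)

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.001, np.zeros(3))

    def test_compose_inverse(self, rng):
        t = random_rigid_transform(rng)
        pts = rng.normal(size=(5, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_matrix_roundtrip(self, rng):
        t = random_rigid_transform(rng)
        t2 = RigidTransform.from_matrix(t.as_matrix())
        assert np.allclose(t2.rotation, t.rotation)
        assert np.allclose(t2.translation, t.translation)

    @settings(max_examples=25, deadline=None)
    @given(
        pts=arrays(np.float64, (6, 3), elements=st.floats(-100, 100)),
        seed=st.integers(0, 10_000),
    )
    def test_distances_preserved(self, pts, seed):
        t = random_rigid_transform(np.random.default_rng(seed))
        mapped = t.apply(pts)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d0 = np.linalg.norm(pts[i] - pts[j])
                d1 = np.linalg.norm(mapped[i] - mapped[j])
                assert abs(d0 - d1) < 1e-9 * max(1.0, d0)


class TestFiducialSet:
    def test_unique_labels_required(self):
        with pytest.raises(ValueError):
            FiducialSet(np.zeros((2, 3)), ["a", "a"])

    def test_collinear_is_degenerate(self):
        pts = np.outer(np.arange(4.0), [1.0, 2.0, 0.5])
        assert _fidset(pts).is_degenerate()

    def test_two_points_degenerate(self):
        assert _fidset(np.array([[0.0, 0, 0], [1.0, 0, 0]])).is_degenerate()

    def test_noncollinear_ok(self):
        assert not _fidset(TETRA).is_degenerate()

    def test_csv_roundtrip(self, tmp_path):
        fs = _fidset(TETRA, frame=Frame.TRACKER)
        path = tmp_path / "fids.csv"
        fs.to_csv(path)
        back = FiducialSet.from_csv(path)
        assert back.labels == fs.labels
        assert back.frame == Frame.TRACKER
        assert np.allclose(back.points, fs.points)


class TestRegisterRigid:
    def test_identity(self):
        src = _fidset(TETRA)
        res = register_rigid(src, _fidset(TETRA))
        assert res.fre < 1e-9
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_translation_recovery(self):
        src = _fidset(TETRA)
        dst = _fidset(TETRA + np.array([5.0, -3.0, 2.0]))
        res = register_rigid(src, dst)
        assert np.allclose(res.transform.translation, [5, -3, 2], atol=1e-9)
        assert res.fre < 1e-9

    def test_rotation_30deg_oracle(self):
        # construct-apply-recover: 6 points, 30 deg about (1,1,1)/sqrt(3)
        pts = np.vstack([TETRA, [[25.0, 30.0, 10.0], [-10.0, 5.0, 20.0]]])
        true = RigidTransform.from_axis_angle([1, 1, 1], np.pi / 6, [4.0, -7.0, 2.5])
        res = register_rigid(_fidset(pts), _fidset(true.apply(pts)))
        err = np.linalg.norm(res.transform.apply(pts) - true.apply(pts), axis=1)
        assert err.max() < 1e-9

    def test_exactness_100_random_transforms(self, rng):
        pts = TETRA
        for _ in range(100):
            true = random_rigid_transform(rng)
            res = register_rigid(_fidset(pts), _fidset(true.apply(pts)))
            assert res.fre < 1e-9

    def test_fre_monte_carlo_band(self):
        # E[FRE^2] ~= (1 - 6/(2N)) * 3 sigma^2 for rigid fits
        rng = np.random.default_rng(7)
        sigma, n = 0.5, 12
        pts = rng.uniform(-100, 100, size=(n, 3))
        src = _fidset(pts)
        fres = []
        for _ in range(1000):
            noisy = pts + rng.normal(0, sigma, size=pts.shape)
            fres.append(register_rigid(src, _fidset(noisy)).fre)
        assert 0.6 < np.mean(fres) < 1.1

    def test_label_mismatch_raises(self):
        src = _fidset(TETRA)
        dst = FiducialSet(TETRA, ["a", "b", "c", "d"])
        with pytest.raises(CorrespondenceError):
            register_rigid(src, dst)

    def test_collinear_raises(self):
        pts = np.outer(np.arange(4.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateConfigurationError):
            register_rigid(_fidset(pts), _fidset(pts))

    def test_no_reflection_on_mirrored_coplanar(self):
        # coplanar square; destination mirrored: unconstrained optimum is a
        # reflection, the solver must still return a proper rotation
        square = np.array(
            [[0.0, 0, 0], [40.0, 0, 0], [40.0, 40, 0], [0.0, 40, 0]]
        )
        mirrored = square * np.array([1.0, -1.0, 1.0]) + np.array([0.0, 0.1, 0.0])
        res = register_rigid(_fidset(square), _fidset(mirrored))
        assert np.linalg.det(res.transform.rotation) > 0.999999999

    def test_result_json_roundtrip(self, tmp_path):
        res = register_rigid(_fidset(TETRA), _fidset(TETRA + 1.0))
        path = tmp_path / "reg.json"
        res.to_json(path)
        back = RegistrationResult.from_json(path)
        assert abs(back.fre - res.fre) < 1e-12
        assert np.allclose(back.transform.as_matrix(), res.transform.as_matrix())


class TestCorrespondenceSearch:
    def test_recovers_shuffled_order(self, rng):
        true = random_rigid_transform(rng)
        dst_pts = true.apply(TETRA)
        perm = [2, 0, 3, 1]
        shuffled = FiducialSet(dst_pts[perm], ["x1", "x2", "x3", "x4"], Frame.TRACKER)
        matched = match_correspondence(_fidset(TETRA), shuffled)
        res = register_rigid(_fidset(TETRA), matched)
        assert res.fre < 1e-9

    def test_rejects_large_sets(self):
        pts = np.random.default_rng(0).normal(size=(9, 3))
        with pytest.raises(ValueError):
            match_correspondence(_fidset(pts), _fidset(pts, prefix="q"))


class TestTargetRegistrationError:
    def test_zero_when_equal(self, rng):
        t = random_rigid_transform(rng)
        reg = RegistrationResult(t, 0.0)
        assert target_registration_error(reg, t, [10.0, 20.0, 30.0]) == 0.0

    def test_three_four_five(self):
        t = RigidTransform.identity()
        reg = RegistrationResult(RigidTransform(np.eye(3), [3.0, 0.0, 4.0]), 0.0)
        assert abs(target_registration_error(reg, t, [7.0, -2.0, 1.0]) - 5.0) < 1e-12

    @staticmethod
    def _mean_tre(n_fiducials, sigma, n_reps, probe, seed):
        rng = np.random.default_rng(seed)
        tres = []
        base = np.random.default_rng(99).uniform(-100, 100, size=(32, 3))
        pts = base[:n_fiducials]
        src = _fidset(pts)
        true = RigidTransform.identity()
        for _ in range(n_reps):
            noisy = pts + rng.normal(0, sigma, size=pts.shape)
            res = register_rigid(src, _fidset(noisy))
            tres.append(target_registration_error(res, true, probe))
        return float(np.mean(tres))

    def test_tre_decreases_with_fiducial_count(self):
        probe = [150.0, 0.0, 50.0]
        means = [
            self._mean_tre(n, sigma=1.0, n_reps=2000, probe=probe, seed=5)
            for n in (4, 8, 16, 32)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_tre_increases_with_noise(self):
        probe = [150.0, 0.0, 50.0]
        means = [
            self._mean_tre(8, sigma=s, n_reps=2000, probe=probe, seed=6)
            for s in (0.25, 0.5, 1.0, 2.0)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))
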