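"""Pinhole projection, least-squares rigid alignment, projection correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmdcalib import rigid_geometry as rg
from hmdcalib.errors import (
    BehindCameraError,
    DegenerateConfigurationError,
    InsufficientCorrespondencesError,
)

from conftest import random_rotation

CAM = rg.CameraModel(fx=500, fy=500, cx=448, cy=252)
IDENTITY = rg.RigidTransform3D.identity()

# four non-coplanar points
TETRA = np.array(
    [[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.0, 0.1, 0.0], [0.0, 0.0, 0.1]]
)


class TestProject:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0.0, 0.0, 1.0), (448.0, 252.0)),  # optical axis -> principal point
            ((0.1, 0.0, 1.0), (498.0, 252.0)),  # u = cx + fx*x/z
            ((0.0, -0.1, 2.0), (448.0, 227.0)),  # v = cy + fy*y/z
        ],
    )
    def test_pinhole_examples(self, point, expected):
        uv = rg.project(CAM, IDENTITY, point)
        np.testing.assert_allclose(uv, expected, atol=1e-12)

    def test_point_behind_camera_rejected(self):
        with pytest.raises(BehindCameraError):
            rg.project(CAM, IDENTITY, (0.0, 0.0, -1.0))

    def test_extrinsics_move_point_into_view(self):
        # camera shifted back by 1 m sees the origin at the principal point
        ext = rg.RigidTransform3D(np.eye(3), [0.0, 0.0, 1.0])
        uv = rg.project(CAM, ext, (0.0, 0.0, 0.0))
        np.testing.assert_allclose(uv, (448.0, 252.0), atol=1e-12)

    def test_projection_matrix_agrees_with_pinhole(self):
        P = CAM.projection()
        uv = P.project((0.03, -0.02, 0.7))
        np.testing.assert_allclose(uv, rg.project(CAM, IDENTITY, (0.03, -0.02, 0.7)))


class TestEstimateRigidTransform:
    def test_identity_on_self_correspondence(self):
        tf, rep = rg.estimate_rigid_transform(rg.CorrespondenceSet(TETRA, TETRA))
        assert tf.is_identity(1e-12)
        assert rep.rms_residual < 1e-12

    def test_recovers_known_transform_exactly(self):
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg z
        t = np.array([0.1, -0.2, 0.05])
        b = TETRA @ R.T + t
        tf, rep = rg.estimate_rigid_transform(rg.CorrespondenceSet(TETRA, b))
        np.testing.assert_allclose(tf.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tf.translation, t, atol=1e-9)
        assert rep.rms_residual < 1e-9

    def test_mirrored_target_still_yields_proper_rotation(self):
        mirrored = TETRA.copy()
        mirrored[:, 2] *= -1  # reflection through z=0
        tf, _ = rg.estimate_rigid_transform(rg.CorrespondenceSet(TETRA, mirrored))
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n", [1, 2])
    def test_too_few_pairs_rejected(self, n):
        with pytest.raises(InsufficientCorrespondencesError):
            rg.estimate_rigid_transform(
                rg.CorrespondenceSet(TETRA[:n], TETRA[:n])
            )

    def test_collinear_sources_rejected(self):
        line = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        with pytest.raises(DegenerateConfigurationError):
            rg.estimate_rigid_transform(rg.CorrespondenceSet(line, line))

    def test_noise_free_recovery_random_instances(self, rng):
        for _ in range(200):
            R = random_rotation(rng)
            t = rng.normal(scale=0.2, size=3)
            a = rng.normal(scale=0.3, size=(rng.integers(3, 8), 3))
            tf, _ = rg.estimate_rigid_transform(rg.CorrespondenceSet(a, a @ R.T + t))
            assert np.linalg.norm(tf.rotation - R) < 1e-9
            assert np.linalg.norm(tf.translation - t) < 1e-9
            assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_least_squares_optimality_brute_force(self, rng):
        """No nearby rigid transform beats the closed-form fit's squared error."""

        def sq_error(R, t, a, b):
            return float(np.sum((a @ R.T + t - b) ** 2))

        from scipy.spatial.transform import Rotation

        for _ in range(5):
            n = rng.integers(3, 6)
            a = rng.normal(scale=0.3, size=(n, 3))
            b = a @ random_rotation(rng).T + rng.normal(scale=0.1, size=3)
            b = b + rng.normal(scale=0.01, size=b.shape)
            tf, _ = rg.estimate_rigid_transform(rg.CorrespondenceSet(a, b))
            best = sq_error(tf.rotation, tf.translation, a, b)
            for _ in range(1000):
                dR = Rotation.from_rotvec(rng.normal(scale=0.05, size=3)).as_matrix()
                Rp = dR @ tf.rotation
                tp = tf.translation + rng.normal(scale=0.005, size=3)
                assert sq_error(Rp, tp, a, b) >= best - 1e-12

    def test_equivariance_under_common_rigid_motion(self, rng):
        """Pre-moving both point sets by G conjugates the estimate: G T G^-1."""
        a = rng.normal(scale=0.3, size=(6, 3))
        T = rg.RigidTransform3D(random_rotation(rng), rng.normal(scale=0.1, size=3))
        b = T.apply(a)
        G = rg.RigidTransform3D(random_rotation(rng), rng.normal(scale=0.1, size=3))
        est, _ = rg.estimate_rigid_transform(
            rg.CorrespondenceSet(G.apply(a), G.apply(b))
        )
        expected = rg.compose(G, rg.compose(T, rg.invert(G)))
        np.testing.assert_allclose(est.rotation, expected.rotation, atol=1e-9)
        np.testing.assert_allclose(est.translation, expected.translation, atol=1e-9)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    rotvec=st.lists(st.floats(-3.0, 3.0), min_size=3, max_size=3),
    trans=st.lists(st.floats(-1.0, 1.0), min_size=3, max_size=3),
    seed=st.integers(0, 2**16),
)
def test_estimate_always_returns_proper_rotation(rotvec, trans, seed):
    """For any generating motion and point cloud the estimate stays on SO(3)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(rotvec).as_matrix()
    a = np.random.default_rng(seed).normal(scale=0.3, size=(5, 3))
    b = a @ R.T + np.asarray(trans)
    tf, _ = rg.estimate_rigid_transform(rg.CorrespondenceSet(a, b))
    np.testing.assert_allclose(tf.rotation.T @ tf.rotation, np.eye(3), atol=1e-9)
    assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(tf.rotation, R, atol=1e-8)


class TestComposeInvert:
    def test_compose_with_identity(self, rng):
        t = rg.RigidTransform3D(random_rotation(rng), rng.normal(size=3))
        out = rg.compose(rg.RigidTransform3D.identity(), t)
        np.testing.assert_allclose(out.rotation, t.rotation)
        np.testing.assert_allclose(out.translation, t.translation)

    def test_invert_rotation(self):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        inv = rg.invert(rg.RigidTransform3D(Rz, np.zeros(3)))
        np.testing.assert_allclose(inv.rotation, Rz.T, atol=1e-15)

    def test_compose_with_inverse_is_identity(self, rng):
        for _ in range(20):
            t = rg.RigidTransform3D(random_rotation(rng), rng.normal(size=3))
            assert rg.compose(t, rg.invert(t)).is_identity(1e-12)
            assert rg.compose(rg.invert(t), t).is_identity(1e-12)


class TestCorrectProjection:
    def test_identity_offset_is_noop(self):
        P = CAM.projection()
        out = rg.correct_projection(P, rg.RigidTransform3D.identity())
        np.testing.assert_allclose(out.P, P.P, atol=1e-15)

    def test_translation_offset_shifts_projection(self):
        # pinhole oracle: 0.01 m lateral offset at 1 m depth moves u by 5 px
        P = CAM.projection()
        off = rg.RigidTransform3D(np.eye(3), [0.01, 0.0, 0.0])
        uv = rg.correct_projection(P, off).project((0.0, 0.0, 1.0))
        np.testing.assert_allclose(uv, (453.0, 252.0), atol=1e-12)

    def test_sequential_corrections_compose(self, rng):
        P = CAM.projection()
        t1 = rg.RigidTransform3D(random_rotation(rng), rng.normal(scale=0.01, size=3))
        t2 = rg.RigidTransform3D(random_rotation(rng), rng.normal(scale=0.01, size=3))
        twice = rg.correct_projection(rg.correct_projection(P, t1), t2)
        once = rg.correct_projection(P, rg.compose(t1, t2))
        np.testing.assert_allclose(twice.P, once.P, atol=1e-12)


class TestFileInterfaces:
    def test_transform_json_roundtrip(self, tmp_path, rng):
        t = rg.RigidTransform3D(
            random_rotation(rng), rng.normal(size=3), "camera", "eye_left"
        )
        path = tmp_path / "t.json"
        rg.save_transform_json(t, path)
        back = rg.load_transform_json(path)
        np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-15)
        np.testing.assert_allclose(back.translation, t.translation, atol=1e-15)
        assert (back.frame_from, back.frame_to) == ("camera", "eye_left")

    def test_correspondence_csv_roundtrip(self, tmp_path, rng):
        sets = [
            rg.CorrespondenceSet(
                rng.normal(size=(5, 3)), rng.normal(size=(5, 3)), eye_label=eye
            )
            for eye in ("left", "right")
        ]
        path = tmp_path / "corr.csv"
        rg.save_correspondences_csv(sets, path)
        back = rg.load_correspondences_csv(path)
        for cs in sets:
            np.testing.assert_allclose(back[cs.eye_label].source, cs.source, atol=1e-7)
            np.testing.assert_allclose(back[cs.eye_label].target, cs.target, atol=1e-7)
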