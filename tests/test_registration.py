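import numpy as np
import pytest

import arterymap as am
from arterymap.registration import (
    N_LANDMARKS,
    CameraModel,
    ConvergenceError,
    DegeneracyError,
    LandmarkSet,
    ProjectionError,
    SimilarityTransform,
    estimate_pose,
)


def _random_landmarks(seed=0, scale=40.0):
    rng = np.random.default_rng(seed)
    return LandmarkSet(points=rng.normal(size=(N_LANDMARKS, 3)) * scale)


def _random_similarity(rng):
    from scipy.spatial.transform import Rotation

    return SimilarityTransform(
        scale=float(rng.uniform(0.5, 2.0)),
        rotation=Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix(),
        translation=rng.normal(size=3) * 20,
    )


class TestLandmarkSet:
    def test_count_enforced(self):
        with pytest.raises(ValueError, match="68"):
            LandmarkSet(points=np.zeros((67, 3)))

    def test_csv_and_json_round_trip(self, tmp_path):
        lm = _random_landmarks(1)
        for name in ("lm.csv", "lm.json"):
            p = tmp_path / name
            lm.write(p)
            back = LandmarkSet.read(p)
            np.testing.assert_allclose(back.points, lm.points, atol=1e-8)


class TestEstimateSimilarity:
    def test_identity_on_self(self):
        lm = _random_landmarks(2)
        xf, rms = am.estimate_similarity(lm, lm)
        assert xf.scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(xf.translation, 0.0, atol=1e-10)
        assert rms < 1e-10

    def test_recovers_known_transform(self):
        lm = _random_landmarks(3)
        th = np.deg2rad(30)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        true = SimilarityTransform(1.2, R, np.array([5.0, -3.0, 2.0]))
        target = LandmarkSet(points=true.apply(lm.points))
        xf, rms = am.estimate_similarity(lm, target)
        assert xf.scale == pytest.approx(1.2, abs=1e-9)
        np.testing.assert_allclose(xf.rotation, R, atol=1e-9)
        np.testing.assert_allclose(xf.translation, true.translation, atol=1e-9)
        assert rms < 1e-9

    def test_noise_free_scale_recovery_across_100_transforms(self):
        lm = _random_landmarks(4)
        rng = np.random.default_rng(42)
        for _ in range(100):
            true = _random_similarity(rng)
            target = LandmarkSet(points=true.apply(lm.points))
            xf, rms = am.estimate_similarity(lm, target)
            assert xf.scale == pytest.approx(true.scale, abs=1e-9)
            assert rms < 1e-9

    def test_noisy_fit_rms_reflects_noise_level(self):
        lm = _random_landmarks(5)
        rng = np.random.default_rng(6)
        true = _random_similarity(rng)
        rmss = []
        for seed in range(10):
            noise = np.random.default_rng(seed).normal(0, 0.5, size=(68, 3))
            target = LandmarkSet(points=true.apply(lm.points) + noise)
            _, rms = am.estimate_similarity(lm, target)
            rmss.append(rms)
        assert 0.3 < np.mean(rmss) < 0.7

    def test_matches_skimage_umeyama(self):
        # independent closed-form implementation in scikit-image
        from skimage.transform import SimilarityTransform as SkSim

        lm = _random_landmarks(7)
        rng = np.random.default_rng(8)
        target = LandmarkSet(
            points=_random_similarity(rng).apply(lm.points)
            + rng.normal(0, 1.0, size=(68, 3))
        )
        xf, _ = am.estimate_similarity(lm, target)
        sk = SkSim.from_estimate(lm.points, target.points)
        M = sk.params
        sk_scale = np.cbrt(np.linalg.det(M[:3, :3]))
        np.testing.assert_allclose(xf.scale, sk_scale, rtol=1e-9)
        np.testing.assert_allclose(xf.rotation, M[:3, :3] / sk_scale, atol=1e-9)
        np.testing.assert_allclose(xf.translation, M[:3, 3], atol=1e-9)

    def test_residual_invariant_under_joint_rigid_motion(self):
        lm = _random_landmarks(9)
        rng = np.random.default_rng(10)
        target = LandmarkSet(points=lm.points + rng.normal(0, 1, size=(68, 3)))
        _, rms0 = am.estimate_similarity(lm, target)
        rigid = _random_similarity(rng)
        rigid = SimilarityTransform(1.0, rigid.rotation, rigid.translation)
        _, rms1 = am.estimate_similarity(
            LandmarkSet(points=rigid.apply(lm.points)),
            LandmarkSet(points=rigid.apply(target.points)),
        )
        assert rms1 == pytest.approx(rms0, abs=1e-9)

    def test_degenerate_input_rejected(self):
        coincident = LandmarkSet(points=np.ones((68, 3)))
        with pytest.raises(DegeneracyError):
            am.estimate_similarity(coincident, _random_landmarks(11))
        line = LandmarkSet(
            points=np.outer(np.linspace(0, 1, 68), np.array([1.0, 2.0, 3.0]))
        )
        with pytest.raises(DegeneracyError):
            am.estimate_similarity(line, _random_landmarks(12))


class TestApplyTransform:
    def test_identity_and_inverse(self):
        lm = _random_landmarks(13)
        ident = SimilarityTransform()
        np.testing.assert_array_equal(
            am.apply_transform(lm, ident).points, lm.points
        )
        rng = np.random.default_rng(14)
        xf = _random_similarity(rng)
        back = am.apply_transform(am.apply_transform(lm, xf), xf.inverse())
        np.testing.assert_allclose(back.points, lm.points, atol=1e-9)

    def test_pairwise_distances_scale_exactly(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(30, 3)) * 10
        xf = _random_similarity(rng)
        out = am.apply_transform(pts, xf)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        np.testing.assert_allclose(d1, xf.scale * d0, rtol=1e-9, atol=1e-9)

    def test_mesh_and_centerline_topology_preserved(self):
        from arterymap.segmentation import CenterlinePolyline
        from arterymap.volume_io import SurfaceMesh

        rng = np.random.default_rng(16)
        mesh = SurfaceMesh(
            vertices=rng.normal(size=(4, 3)),
            faces=[[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]],
        )
        xf = _random_similarity(rng)
        out = am.apply_transform(mesh, xf)
        np.testing.assert_array_equal(out.faces, mesh.faces)
        line = CenterlinePolyline(points=rng.normal(size=(5, 3)), label="Fa-left")
        out2 = am.apply_transform(line, xf)
        assert out2.label == "Fa-left"
        assert len(out2.points) == 5


class TestProjectPoints:
    CAM = CameraModel(fx=1000.0, fy=900.0, cx=500.0, cy=400.0)

    def test_optical_axis_hits_principal_point(self):
        for z in (1.0, 10.0, 500.0):
            uv = am.project_points(np.array([[0.0, 0.0, z]]), self.CAM)
            np.testing.assert_allclose(uv[0], [500.0, 400.0])

    def test_formula_example(self):
        uv = am.project_points(np.array([[10.0, 0.0, 100.0]]), self.CAM)
        assert uv[0, 0] == pytest.approx(1000.0 * 0.1 + 500.0)

    def test_point_behind_camera_rejected_with_indices(self):
        pts = np.array([[0, 0, 10.0], [0, 0, 0.0], [0, 0, -5.0]])
        with pytest.raises(ProjectionError, match=r"\[1, 2\]"):
            am.project_points(pts, self.CAM)


class TestPoseRecovery:
    def _scene(self, seed=0):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        model = _random_landmarks(seed, scale=30.0)
        R = Rotation.from_euler(
            "xyz", rng.uniform(-20, 20, size=3), degrees=True
        ).as_matrix()
        t = np.array([5.0, -8.0, 400.0]) + rng.normal(0, 5, 3)
        cam = CameraModel(fx=1200, fy=1200, cx=400, cy=400)
        pc = model.points @ R.T + t
        uv = np.column_stack(
            [1200 * pc[:, 0] / pc[:, 2] + 400, 1200 * pc[:, 1] / pc[:, 2] + 400]
        )
        return model, LandmarkSet(points=uv), cam, R, t

    def test_noise_free_pose_recovered(self):
        model, view, cam, R, t = self._scene(17)
        reg = am.register_model_to_view(model, view, cam)
        assert reg["mean_reprojection_error_px"] < 1e-6
        np.testing.assert_allclose(reg["pose_rotation"], R, atol=1e-6)
        np.testing.assert_allclose(reg["pose_translation"], t, rtol=1e-5)

    def test_identity_pose_recovered(self):
        model = _random_landmarks(18, scale=30.0)
        shifted = LandmarkSet(points=model.points + [0, 0, 500.0])
        cam = CameraModel(fx=1000, fy=1000, cx=300, cy=300)
        uv = am.project_points(shifted.points, cam)
        reg = am.register_model_to_view(shifted, LandmarkSet(points=uv), cam)
        np.testing.assert_allclose(reg["pose_rotation"], np.eye(3), atol=1e-7)
        np.testing.assert_allclose(reg["pose_translation"], 0.0, atol=1e-4)

    def test_pixel_noise_gives_commensurate_residual(self):
        model, view, cam, R, t = self._scene(19)
        noisy = LandmarkSet(
            points=view.points + np.random.default_rng(20).normal(0, 1, (68, 2))
        )
        reg = am.register_model_to_view(model, noisy, cam)
        assert 0.5 < reg["mean_reprojection_error_px"] < 2.0

    def test_projection_consistency_with_registration_landmarks(self):
        # projecting the posed model reproduces the view up to the residual
        model, view, cam, R, t = self._scene(21)
        reg = am.register_model_to_view(model, view, cam)
        err = np.linalg.norm(reg["projected_landmarks"] - view.points, axis=1)
        assert err.mean() <= reg["mean_reprojection_error_px"] + 1e-9

    def test_curves_projected_with_pose(self):
        from arterymap.segmentation import CenterlinePolyline

        model, view, cam, R, t = self._scene(22)
        line = CenterlinePolyline(
            points=model.points[:5] * 0.5 + [0, 0, 1.0], label="ST-left"
        )
        reg = am.register_model_to_view(model, view, cam, [line])
        assert len(reg["projected_curves"]) == 1
        lab, pts = reg["projected_curves"][0]
        assert lab == "ST-left" and pts.shape == (5, 2)
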