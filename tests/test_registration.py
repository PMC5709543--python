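import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from condylometry.registration import (
    LandmarkSet,
    RigidTransform,
    apply_transform,
    define_ramus_region,
    icp_refine,
    landmark_align,
)
from condylometry.volume_io import GeometryError

from _helpers import grid_surface_mesh, icosphere_mesh


def _lm(points, names=None, side="left"):
    points = np.asarray(points, dtype=float)
    names = names or [f"p{i}" for i in range(len(points))]
    return LandmarkSet(names, points, side)


def _random_rigid(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.uniform(-10, 10, 3))


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse_round_trip(self, rng):
        T = _random_rigid(rng)
        pts = rng.normal(size=(50, 3))
        back = T.inverse().apply(T.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_isometry(self, rng):
        """Rigid maps preserve all pairwise distances."""
        T = _random_rigid(rng)
        pts = rng.normal(size=(40, 3)) * 5
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        moved = T.apply(pts)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9


class TestLandmarkAlign:
    def test_identity(self):
        pts = [[0, 0, 0], [10, 0, 0], [0, 8, 0], [0, 0, 6]]
        T = landmark_align(_lm(pts), _lm(pts))
        assert T.rotation_angle_deg() < 1e-10
        assert np.linalg.norm(T.translation) < 1e-10

    def test_recovers_known_transform(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 8, 0], [3, 3, 6]], dtype=float)
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        T_true = RigidTransform(R, np.array([5.0, -2.0, 1.0]))
        T = landmark_align(_lm(pts), _lm(T_true.apply(pts)))
        assert np.abs(T.rotation - R).max() < 1e-8
        assert np.abs(T.translation - T_true.translation).max() < 1e-8

    def test_reflection_excluded(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 8, 0], [3, 3, 6]], dtype=float)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        T = landmark_align(_lm(pts), _lm(mirrored))
        assert np.isclose(np.linalg.det(T.rotation), 1.0, atol=1e-8)
        residual = np.linalg.norm(T.apply(pts) - mirrored, axis=1)
        assert residual.max() > 1.0  # a proper rotation cannot fit a mirror image

    def test_collinear_rejected(self):
        pts = [[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]]
        with pytest.raises(GeometryError):
            landmark_align(_lm(pts), _lm(pts))

    @pytest.mark.parametrize("case", range(5))
    def test_matches_direct_minimization_oracle(self, case):
        """The closed-form SVD fit equals an independent numerical
        minimization over the rotation-vector parameterization."""
        rng = np.random.default_rng(100 + case)
        n = int(rng.integers(3, 6))
        M = rng.uniform(-10, 10, (n, 3))
        while np.linalg.svd(M - M.mean(0), compute_uv=False)[1] < 1e-3:
            M = rng.uniform(-10, 10, (n, 3))
        F = _random_rigid(rng).apply(M) + rng.normal(0, 0.3, (n, 3))
        T = landmark_align(_lm(M), _lm(F))

        def objective(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            return np.sum((M @ R.T + p[3:] - F) ** 2)

        best = None
        for k in range(8):
            r0 = Rotation.random(random_state=k).as_rotvec()
            res = minimize(objective, np.concatenate([r0, F.mean(0) - M.mean(0)]),
                           method="Nelder-Mead",
                           options={"maxiter": 8000, "xatol": 1e-12, "fatol": 1e-14})
            if best is None or res.fun < best.fun:
                best = res
        closed_form = np.sum((T.apply(M) - F) ** 2)
        assert closed_form <= best.fun + 1e-9
        R_oracle = Rotation.from_rotvec(best.x[:3]).as_matrix()
        angle = Rotation.from_matrix(T.rotation.T @ R_oracle).magnitude()
        assert angle < 1e-3


class TestICP:
    def _bumpy_mesh(self):
        return grid_surface_mesh(
            40, 40, 20.0, height=lambda x, y: 1.5 * np.sin(0.8 * x) * np.cos(0.6 * y)
        )

    def test_self_registration_is_identity(self):
        mesh = self._bumpy_mesh()
        res = icp_refine(mesh, mesh, max_iter=10)
        assert res.rms < 1e-9
        assert res.transform.rotation_angle_deg() < 1e-6
        assert np.linalg.norm(res.transform.translation) < 1e-6

    def test_recovers_known_transform(self):
        mesh = self._bumpy_mesh()
        R = Rotation.from_euler("zy", [5.0, -3.0], degrees=True).as_matrix()
        T_true = RigidTransform(R, np.array([2.0, -1.0, 0.5]))
        fixed = apply_transform(mesh, T_true)
        res = icp_refine(mesh, fixed, max_iter=60, tol=1e-7)
        err = res.transform.compose(T_true.inverse())
        moved = T_true.apply(mesh.vertices)
        disp = np.linalg.norm(err.apply(moved) - moved, axis=1)
        assert err.rotation_angle_deg() < 0.05
        assert disp.mean() < 0.02

    def test_rms_history_non_increasing(self):
        mesh = self._bumpy_mesh()
        T = RigidTransform(Rotation.from_euler("z", 4, degrees=True).as_matrix(), np.array([1.0, 0.5, 0]))
        res = icp_refine(mesh, apply_transform(mesh, T), max_iter=40)
        assert all(a >= b - 1e-12 for a, b in zip(res.rms_history, res.rms_history[1:]))

    def test_empty_region_errors(self):
        mesh = self._bumpy_mesh()
        with pytest.raises(GeometryError):
            icp_refine(mesh, mesh, region=np.zeros(mesh.n_vertices, dtype=bool))


class TestRamusRegion:
    def test_all_vertices_at_large_radius(self):
        mesh = icosphere_mesh(5.0)
        lm = _lm([[0, 0, 0]], names=["ramus"])
        sel = define_ramus_region(mesh, lm, radius=1e9)
        assert sel.all()

    def test_tiny_radius_errors(self):
        mesh = icosphere_mesh(5.0)
        lm = _lm([[0, 0, 100]], names=["ramus"])
        with pytest.raises(GeometryError):
            define_ramus_region(mesh, lm, radius=1e-6)

    def test_phantom_region_excludes_condylar_head(self, default_phantom):
        """No vertex of the generator's condylar-head label enters the fit."""
        from condylometry import segmentation as seg
        from condylometry.phantom import TRABECULAR

        pre, _, truth = default_phantom
        dec = seg.suggest_threshold(pre)
        comp = seg.extract_mandible_component(seg.segment_bone(pre, dec))
        mesh = seg.threshold_isosurface(pre, dec, comp)
        sel = define_ramus_region(mesh, truth.landmarks_pre)
        # head-region voxel coordinates, conservatively dilated by one voxel
        spec = truth.spec
        hc = np.asarray(spec.head_center)
        semi = np.asarray(spec.head_semiaxes) + 0.5
        v = mesh.vertices[sel]
        inside_head = (
            ((v - hc) / semi) ** 2
        ).sum(axis=1) <= 1.0
        assert not inside_head.any()


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    rotvec=st.tuples(*[st.floats(-3.0, 3.0) for _ in range(3)]),
    trans=st.tuples(*[st.floats(-20.0, 20.0) for _ in range(3)]),
)
def test_rigid_transform_group_properties(rotvec, trans):
    """Any rigid transform is an isometry and inverts exactly."""
    R = Rotation.from_rotvec(np.asarray(rotvec)).as_matrix()
    T = RigidTransform(R, np.asarray(trans))
    pts = np.array([[0.0, 0, 0], [3, -2, 7], [10, 10, -4], [-6, 1, 2]])
    moved = T.apply(pts)
    d0 = np.linalg.norm(pts[0] - pts[1])
    assert abs(np.linalg.norm(moved[0] - moved[1]) - d0) < 1e-9
    assert np.abs(T.inverse().apply(moved) - pts).max() < 1e-8
    assert abs(np.linalg.det(T.compose(T.inverse()).rotation) - 1.0) < 1e-10


def test_apply_transform_types(rng):
    T = _random_rigid(rng)
    lm = _lm([[0, 0, 0], [1, 2, 3], [4, 5, 6]])
    out = apply_transform(lm, T)
    assert out.names == lm.names
    assert np.abs(out.points - T.apply(lm.points)).max() < 1e-12
    mesh = icosphere_mesh(2.0)
    mout = apply_transform(mesh, T)
    assert np.abs(mout.vertices - T.apply(mesh.vertices)).max() < 1e-12
    np.testing.assert_array_equal(mout.faces, mesh.faces)
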