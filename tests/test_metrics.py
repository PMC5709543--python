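import numpy as np
import pytest

from condylometry import metrics
from condylometry.metrics import (
    accuracy_vs_gold,
    boundary_polylines,
    distance_to_curve,
    extract_lower_border,
    part_comparison,
    subtract_voi_mismatch,
)
from condylometry.segmentation import BinaryMask
from condylometry.voi import SphereVOI
from condylometry.volume_io import GeometryError, InputError, SurfaceMesh

from _helpers import (
    brute_force_mesh_distance,
    grid_surface_mesh,
    icosphere_mesh,
    open_cylinder_mesh,
    random_triangle_mesh,
)


class TestPartComparison:
    def test_identity_is_zero(self):
        mesh = icosphere_mesh(3.0)
        s = part_comparison(mesh, mesh)
        assert s.mean == 0.0 and s.sd == 0.0 and s.max == 0.0
        assert s.n == mesh.n_vertices

    def test_parallel_planes(self):
        """Query square hovering 0.3 mm over the interior of a larger
        reference square: every vertex distance is exactly 0.3."""
        ref = grid_surface_mesh(8, 8, 30.0, z0=0.0)
        query = grid_surface_mesh(6, 6, 10.0, z0=0.3)
        query.vertices[:, :2] += 10.0  # center over the reference interior
        s = part_comparison(query, ref)
        assert s.mean == pytest.approx(0.3, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("case", range(50))
    def test_matches_brute_force_oracle(self, case):
        """Spatial-index distances equal the exhaustive all-triangle scan."""
        rng = np.random.default_rng(1000 + case)
        ref = random_triangle_mesh(rng, n_faces=int(rng.integers(4, 30)))
        query_pts = rng.uniform(-3, 3, (12, 3))
        query = SurfaceMesh(query_pts, [[0, 1, 2]])
        s = part_comparison(query, ref)
        oracle = brute_force_mesh_distance(query_pts, ref)
        assert np.abs(s.distances - oracle).max() < 1e-9

    def test_translation_bound(self, rng):
        """Translating the query by d changes the mean distance by at most d."""
        ref = random_triangle_mesh(rng, n_faces=20)
        query = SurfaceMesh(rng.uniform(-3, 3, (30, 3)), [[0, 1, 2]])
        base = part_comparison(query, ref).mean
        d = 0.7
        shifted = SurfaceMesh(query.vertices + [d, 0, 0], [[0, 1, 2]])
        moved = part_comparison(shifted, ref).mean
        assert abs(moved - base) <= d + 1e-12

    def test_attaches_vertex_distances(self):
        ref = icosphere_mesh(3.0)
        q = icosphere_mesh(3.5)
        part_comparison(q, ref)
        assert q.vertex_attr is not None and len(q.vertex_attr) == q.n_vertices

    def test_exceed_fraction_uses_one_voxel_cutoff(self):
        ref = grid_surface_mesh(6, 6, 10.0, z0=0.0)
        near = grid_surface_mesh(3, 3, 4.0, z0=0.2)
        near.vertices[:, :2] += 3.0
        far = grid_surface_mesh(3, 3, 4.0, z0=0.5)
        far.vertices[:, :2] += 3.0
        assert part_comparison(near, ref).threshold_exceed_fraction == 0.0
        assert part_comparison(far, ref).threshold_exceed_fraction == 1.0

    def test_empty_mesh_rejected(self):
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(InputError):
            part_comparison(empty, icosphere_mesh(1.0))


class TestLowerBorder:
    def test_open_cylinder_lower_rim(self):
        mesh = open_cylinder_mesh(radius=7.0, z0=2.0, z1=10.0, n_theta=120)
        border = extract_lower_border(mesh)
        assert np.allclose(border[:, 2], 2.0)
        seglen = np.linalg.norm(np.diff(border, axis=0), axis=1).sum()
        assert abs(seglen - 2 * np.pi * 7.0) / (2 * np.pi * 7.0) < 0.01

    def test_watertight_mesh_rejected(self):
        with pytest.raises(GeometryError):
            boundary_polylines(icosphere_mesh(2.0))

    def test_border_vertices_lie_on_crop_sphere(self, default_phantom):
        """Cropping by the VOI leaves a rim sitting on the sphere."""
        from condylometry import segmentation as seg
        from condylometry.pipeline import _crop_mesh_to_sphere
        from condylometry.voi import fit_condylar_sphere, lowest_notch_point

        pre, _, truth = default_phantom
        dec = seg.suggest_threshold(pre)
        comp = seg.extract_mandible_component(seg.segment_bone(pre, dec))
        mesh = seg.threshold_isosurface(pre, dec, comp)
        n = lowest_notch_point(mesh, truth.landmarks_pre)
        voi = fit_condylar_sphere(
            mesh, n, truth.landmarks_pre.get("condyle"), plane_offset=0.4
        )
        cropped = _crop_mesh_to_sphere(mesh, voi)
        border = extract_lower_border(cropped)
        d = np.linalg.norm(border - voi.center, axis=1)
        # border vertices are the survivors adjacent to the cut: inside,
        # within one mesh edge length of the sphere
        assert (d <= voi.radius + 1e-9).all()
        assert (voi.radius - d.min()) < 1.0


class TestDistanceToCurve:
    def test_identical_curves(self):
        t = np.linspace(0, 2 * np.pi, 100)
        c = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        assert distance_to_curve(c, c).mean < 1e-15

    def test_concentric_circles(self):
        t = np.linspace(0, 2 * np.pi, 361)
        a = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
        b = np.column_stack([11 * np.cos(t), 11 * np.sin(t), np.zeros_like(t)])
        s = distance_to_curve(a, b)
        assert s.mean == pytest.approx(1.0, rel=0.005)

    def test_parallel_segments_exact(self):
        a = np.array([[0, 0, 0], [10, 0, 0.0]])
        b = np.array([[-5, 0.7, 0], [15, 0.7, 0.0]])
        s = distance_to_curve(a, b)
        assert s.mean == pytest.approx(0.7, abs=1e-12)
        assert s.max == pytest.approx(0.7, abs=1e-12)

    def test_reparameterization_invariance(self):
        t = np.linspace(0, 2 * np.pi, 181)
        a = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
        b = np.column_stack([11 * np.cos(t), 11 * np.sin(t), np.zeros_like(t)])
        t2 = np.linspace(0, 2 * np.pi, 361)
        b2 = np.column_stack([11 * np.cos(t2), 11 * np.sin(t2), np.zeros_like(t2)])
        m1 = distance_to_curve(a, b).mean
        m2 = distance_to_curve(a, b2).mean
        assert abs(m1 - m2) < 2e-3

    def test_single_point_curve_rejected(self):
        with pytest.raises(InputError):
            distance_to_curve(np.zeros((1, 3)), np.zeros((5, 3)))


class TestSubtractVoiMismatch:
    def _mask(self, rng):
        return BinaryMask(rng.random((24, 24, 24)) < 0.5, (0.5,) * 3, (0.0, 0.0, 0.0))

    def test_equal_vois_keep_in_sphere_content(self, rng):
        a, b = self._mask(rng), self._mask(rng)
        c = np.array([6.0, 6.0, 6.0])
        voi = SphereVOI(c, 4.0, c + [0, 0, 4.0])
        out_a, out_b = subtract_voi_mismatch(a, voi, b, voi)
        from condylometry.voi import crop_to_sphere

        np.testing.assert_array_equal(out_a.voxels, crop_to_sphere(a, voi).voxels)

    def test_offset_spheres_intersection_only(self, rng):
        a, b = self._mask(rng), self._mask(rng)
        c1 = np.array([5.0, 6.0, 6.0])
        c2 = np.array([8.0, 6.0, 6.0])
        v1 = SphereVOI(c1, 3.0, c1 + [0, 0, 3.0])
        v2 = SphereVOI(c2, 3.0, c2 + [0, 0, 3.0])
        out_a, out_b = subtract_voi_mismatch(a, v1, b, v2)
        for out, src in ((out_a, a), (out_b, b)):
            idx = np.argwhere(out.voxels)
            world = idx * 0.5
            assert (np.linalg.norm(world - c1, axis=1) <= 3.0 + 1e-12).all()
            assert (np.linalg.norm(world - c2, axis=1) <= 3.0 + 1e-12).all()

    def test_disjoint_spheres_rejected(self, rng):
        a, b = self._mask(rng), self._mask(rng)
        c1, c2 = np.array([2.0, 2, 2]), np.array([11.0, 11, 11])
        v1 = SphereVOI(c1, 2.0, c1 + [0, 0, 2.0])
        v2 = SphereVOI(c2, 2.0, c2 + [0, 0, 2.0])
        with pytest.raises(GeometryError):
            subtract_voi_mismatch(a, v1, b, v2)


class TestAccuracyVsGold:
    def _ball_mask(self, r_mm=3.0, spacing=0.1, margin=1.0):
        n = int(np.ceil(2 * (r_mm + margin) / spacing))
        idx = np.indices((n, n, n))
        c = (n - 1) / 2
        inside = (((idx - c) * spacing) ** 2).sum(axis=0) <= r_mm**2
        return BinaryMask(inside, (spacing,) * 3, (0.0, 0.0, 0.0))

    def test_identical_masks(self):
        gold = self._ball_mask(r_mm=2.0, spacing=0.2)
        res = accuracy_vs_gold(gold, gold)
        assert res.distances.mean == 0.0
        assert res.volume_excess == 0.0
        assert res.distances.direction == "test->gold"

    def test_one_voxel_dilation(self):
        """Test = gold with its surface pushed out by one working voxel
        (0.4 mm, Euclidean dilation on a finer grid): the part-comparison
        mean recovers 0.4 mm and the volume excess is positive."""
        from scipy import ndimage

        gold = self._ball_mask(r_mm=3.0, spacing=0.1)
        outside_dist = ndimage.distance_transform_edt(~gold.voxels, sampling=gold.spacing)
        dilated = BinaryMask(outside_dist <= 0.4, gold.spacing, gold.origin)
        res = accuracy_vs_gold(dilated, gold)
        assert res.volume_excess > 0
        assert 0.32 <= res.distances.mean <= 0.48  # 0.4 mm +- 20%
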