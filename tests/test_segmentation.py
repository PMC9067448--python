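import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

import arterymap as am
from arterymap.segmentation import (
    BinaryMask,
    CenterlinePolyline,
    GridMismatchError,
    SegmentationFailureError,
)
from arterymap.vesselness import VesselnessMap
from arterymap.volume_io import EmptyGeometryError, ImageVolume


def _vmap(arr, spacing=(1.0, 1.0, 1.0)):
    return VesselnessMap(
        response=np.asarray(arr, float), scales_used=(1.0,), tau=0.5,
        spacing=spacing,
    )


class TestThresholdSegment:
    def test_zero_map_yields_empty_mask(self):
        mask = am.threshold_segment(_vmap(np.zeros((4, 4, 4))), 0.5)
        assert mask.count == 0

    def test_exact_selection_of_values(self):
        arr = np.zeros((3, 3, 3))
        arr[0, 0, 0], arr[1, 1, 1], arr[2, 2, 2] = 0.2, 0.6, 0.9
        mask = am.threshold_segment(_vmap(arr), 0.5)
        assert mask.count == 2
        assert mask.data[1, 1, 1] and mask.data[2, 2, 2]
        assert not mask.data[0, 0, 0]

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        arr = rng.random((9, 9, 9))
        mask = am.threshold_segment(_vmap(arr), 0.37)
        assert mask.count == sum(
            1 for v in arr.ravel() if v >= 0.37
        )

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        arr = rng.random((8, 8, 8))
        counts = [
            am.threshold_segment(_vmap(arr), t).count
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.7])
    def test_out_of_range_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            am.threshold_segment(_vmap(np.zeros((2, 2, 2))), bad)


class TestSubcutaneousBand:
    def _ball_volume(self, radius=20.0, sp=1.0, n=50):
        ax = np.arange(n) * sp
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        c = (n - 1) * sp / 2
        r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
        return ImageVolume((r <= radius) * 100.0, spacing=(sp, sp, sp)), r

    def test_ball_band_matches_analytic_shell(self):
        vol, r = self._ball_volume(radius=20.0)
        band = am.subcutaneous_band_mask(vol, 5.0)
        # every band voxel within one voxel of the analytic 15..20mm shell
        assert np.all(r[band.data] >= 15.0 - 1.0)
        assert np.all(r[band.data] <= 20.0 + 1.0)
        # and the core of the analytic shell is fully covered
        core = (r >= 16.0) & (r <= 19.0)
        assert np.all(band.data[core])

    def test_band_saturates_to_whole_head(self):
        vol, r = self._ball_volume(radius=10.0, n=30)
        band = am.subcutaneous_band_mask(vol, 50.0)
        head = vol.data > 0
        assert np.array_equal(band.data, head)

    def test_skin_offset_excludes_outer_shell(self):
        vol, r = self._ball_volume(radius=20.0)
        band = am.subcutaneous_band_mask(vol, 5.0, skin_offset_mm=2.0)
        inner = am.subcutaneous_band_mask(vol, 5.0)
        assert band.count < inner.count
        assert np.all(inner.data[band.data])  # still a subset of the full band

    def test_empty_volume_fails(self):
        with pytest.raises(SegmentationFailureError):
            am.subcutaneous_band_mask(ImageVolume(np.zeros((8, 8, 8))), 5.0)


class TestSeparateSuperficial:
    def test_intersection_with_band(self):
        tube = np.zeros((20, 8, 8), bool)
        tube[:, 4, 4] = True
        band = np.zeros_like(tube)
        band[:10] = True
        out = am.separate_superficial(
            BinaryMask(tube), BinaryMask(band), min_component_voxels=1
        )
        assert out.count == 10
        assert np.all(out.data[:10, 4, 4])

    def test_small_components_removed(self):
        arr = np.zeros((30, 10, 10), bool)
        arr[:5, 2, 2] = True  # 5-voxel component
        arr[10:, 5:, 5:] = True  # 500-voxel component
        band = BinaryMask(np.ones_like(arr))
        out = am.separate_superficial(BinaryMask(arr), band, 50)
        assert out.count == 500
        assert not out.data[:5, 2, 2].any()

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.random((12, 12, 12)) > 0.7
        b = rng.random((12, 12, 12)) > 0.3
        out = am.separate_superficial(BinaryMask(a), BinaryMask(b), 4)
        inter = a & b
        labels, n = ndimage.label(inter, structure=np.ones((3, 3, 3)))
        expect = np.zeros_like(inter)
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() >= 4:
                expect |= comp
        assert np.array_equal(out.data, expect)
        # subset invariants hold exactly
        assert np.all(a[out.data]) and np.all(b[out.data])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            am.separate_superficial(
                BinaryMask(np.zeros((4, 4, 4), bool)),
                BinaryMask(np.zeros((5, 5, 5), bool)),
            )


class TestMarchingCubes:
    # the raw binary iso-surface is a staircase: its area systematically
    # overshoots a smooth ball's (~9% here); the clamped pre-smoothing
    # option recovers the analytic area to within a few percent
    @pytest.mark.parametrize("sigma,rel", [(0.0, 0.11), (0.8, 0.05)])
    def test_ball_mesh_closed_with_spherical_area(self, sigma, rel):
        n, sp, radius = 48, 0.5, 8.0
        ax = np.arange(n) * sp
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        c = (n - 1) * sp / 2
        ball = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius**2
        mesh = am.marching_cubes_mesh(
            BinaryMask(ball, spacing=(sp, sp, sp)), smooth_sigma_vox=sigma
        )
        # Euler characteristic 2 for a closed genus-0 surface
        n_edges = len(
            {tuple(sorted(e)) for f in mesh.faces
             for e in ((f[0], f[1]), (f[1], f[2]), (f[0], f[2]))}
        )
        assert len(mesh.vertices) - n_edges + mesh.n_faces == 2
        assert mesh.area() == pytest.approx(4 * np.pi * radius**2, rel=rel)

    def test_single_voxel_encloses_subvoxel_volume(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[2, 2, 2] = True
        mesh = am.marching_cubes_mesh(BinaryMask(arr, spacing=(1, 1, 1)))
        assert 0.125 <= abs(mesh.enclosed_volume()) <= 1.0

    def test_vertices_near_foreground(self):
        rng = np.random.default_rng(4)
        arr = ndimage.binary_dilation(rng.random((12, 12, 12)) > 0.97)
        if not arr.any():
            arr[5, 5, 5] = True
        mask = BinaryMask(arr, spacing=(0.5, 0.5, 0.5))
        mesh = am.marching_cubes_mesh(mask)
        fg = np.argwhere(arr) * 0.5
        d, _ = cKDTree(fg).query(mesh.vertices)
        assert d.max() <= np.linalg.norm([0.5, 0.5, 0.5]) + 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyGeometryError):
            am.marching_cubes_mesh(BinaryMask(np.zeros((4, 4, 4), bool)))


class TestSkeletonize:
    def _tube_mask(self, length_vox=80, sp=0.5, r_vox=3, axis=0):
        shape = [12, 12, 12]
        shape[axis] = length_vox
        arr = np.zeros(shape, bool)
        ax0 = np.arange(shape[0])
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        others = [g for i, g in enumerate(grids) if i != axis]
        d2 = (others[0] - 6) ** 2 + (others[1] - 6) ** 2
        arr = d2 <= r_vox**2
        return BinaryMask(arr, spacing=(sp, sp, sp))

    def test_straight_tube_recovers_axis(self):
        mask = self._tube_mask(length_vox=80, sp=0.5)
        lines = am.skeletonize_centerlines(mask, min_branch_mm=3.0)
        assert len(lines) == 1
        pts = lines[0].points
        # every point within one voxel diagonal of the true axis (y=z=3mm)
        d = np.sqrt((pts[:, 1] - 3.0) ** 2 + (pts[:, 2] - 3.0) ** 2)
        assert d.max() <= np.linalg.norm([0.5, 0.5, 0.5])
        assert lines[0].length_mm() == pytest.approx(40.0, rel=0.10)

    def test_y_junction_splits_into_three_branches(self):
        arr = np.zeros((40, 40, 9), bool)
        arr[:20, 20, 4] = True           # stem
        for i in range(20):              # two diagonal arms
            arr[20 + i, 20 + i, 4] = True
            arr[20 + i, 20 - i, 4] = True
        arr = ndimage.binary_dilation(arr, np.ones((3, 3, 3)))
        lines = am.skeletonize_centerlines(
            BinaryMask(arr, spacing=(0.5, 0.5, 0.5)), min_branch_mm=2.0
        )
        assert len(lines) == 3

    def test_ball_yields_no_branches(self):
        n = 15
        X, Y, Z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        ball = (X - 7) ** 2 + (Y - 7) ** 2 + (Z - 7) ** 2 <= 36
        lines = am.skeletonize_centerlines(
            BinaryMask(ball, spacing=(1, 1, 1)), min_branch_mm=10.0
        )
        assert lines == []

    def test_deterministic_across_runs(self):
        mask = self._tube_mask()
        a = am.skeletonize_centerlines(mask, 3.0)
        b = am.skeletonize_centerlines(mask, 3.0)
        assert len(a) == len(b)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.points, lb.points)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyGeometryError):
            am.skeletonize_centerlines(BinaryMask(np.zeros((3, 3, 3), bool)), 1.0)


class TestPhantomFidelity:
    def test_noisefree_chain_recovers_planted_centerline(self, noisefree_tube_run):
        run = noisefree_tube_run
        truth_pts = np.vstack([v.path_mm for v in run["truth"].vessels])
        skel = np.vstack([l.points for l in run["lines"]])
        d, _ = cKDTree(truth_pts).query(skel)
        voxdiag = run["vol"].voxel_diagonal_mm
        assert d.mean() < voxdiag
        # the planted line is covered end to end as well
        d2, _ = cKDTree(skel).query(truth_pts)
        assert d2.mean() < voxdiag

    def test_no_centerline_outside_band(self, noisefree_tube_run):
        run = noisefree_tube_run
        band = run["band"]
        sp = np.asarray(band.spacing)
        for line in run["lines"]:
            idx = np.round(line.points / sp).astype(int)
            assert band.data[tuple(idx.T)].all()
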