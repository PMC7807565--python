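"""Geometry layer: rasterization, signed distance maps, resampling."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ovhqa.grid import (
    StructureMask,
    VoxelGrid,
    rasterize_contours,
    resample_to_grid,
    signed_distance_map,
)


def naive_point_in_polygon(px: float, py: float, verts: np.ndarray) -> bool:
    """Independent scalar even-odd crossing test (oracle)."""
    inside = False
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        if (y0 > py) != (y1 > py):
            xint = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if px < xint:
                inside = not inside
    return inside


def brute_signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """O(N^2) all-pairs signed distance between voxel centers (oracle)."""
    pts = np.argwhere(np.ones_like(mask)).astype(float) * np.asarray(spacing)
    inside = mask.ravel()
    d_in = cdist(pts, pts[inside]).min(axis=1)
    d_out = cdist(pts, pts[~inside]).min(axis=1)
    out = np.where(inside, -d_out, d_in)
    return out.reshape(mask.shape)


@pytest.fixture
def grid_1mm():
    return VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(3, 20, 20))


class TestRasterize:
    def test_square_on_voxel_center_lines(self, grid_1mm):
        square = np.array([[3.0, 3.0], [13.0, 3.0], [13.0, 13.0], [3.0, 13.0]])
        mask = rasterize_contours([(1.0, square)], grid_1mm)
        assert mask.voxels[1].sum() == 100
        assert mask.voxels[0].sum() == 0 and mask.voxels[2].sum() == 0

    def test_empty_contour_list(self, grid_1mm):
        mask = rasterize_contours([], grid_1mm)
        assert not mask.voxels.any()
        assert mask.volume_cm3 == 0.0

    def test_square_with_hole_xor(self, grid_1mm):
        outer = np.array([[3.0, 3.0], [13.0, 3.0], [13.0, 13.0], [3.0, 13.0]])
        inner = np.array([[6.0, 6.0], [10.0, 6.0], [10.0, 10.0], [6.0, 10.0]])
        mask = rasterize_contours([(1.0, outer), (1.0, inner)], grid_1mm)
        assert mask.voxels[1].sum() == 100 - 16

    @pytest.mark.parametrize("rotation", [0, 1, 3])
    def test_vertex_rotation_invariance(self, grid_1mm, rotation):
        rng = np.random.default_rng(5)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 7))
        radii = rng.uniform(3, 8, 7)
        verts = np.column_stack(
            [9 + radii * np.cos(angles), 9 + radii * np.sin(angles)]
        )
        ref = rasterize_contours([(1.0, verts)], grid_1mm).voxels
        rot = rasterize_contours([(1.0, np.roll(verts, rotation, axis=0))], grid_1mm).voxels
        assert np.array_equal(ref, rot)

    def test_matches_naive_oracle_on_random_polygons(self, grid_1mm):
        rng = np.random.default_rng(17)
        for _ in range(5):
            angles = np.sort(rng.uniform(0, 2 * np.pi, 6))
            radii = rng.uniform(2, 9, 6)
            verts = np.column_stack(
                [10 + radii * np.cos(angles), 10 + radii * np.sin(angles)]
            )
            mask = rasterize_contours([(0.0, verts)], grid_1mm).voxels[0]
            expected = np.array(
                [
                    [naive_point_in_polygon(float(x), float(y), verts) for x in range(20)]
                    for y in range(20)
                ]
            )
            assert np.array_equal(mask, expected)

    def test_z_mismatch_names_the_plane(self, grid_1mm):
        tri = np.array([[1.0, 1.0], [5.0, 1.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="7.3"):
            rasterize_contours([(7.3, tri)], grid_1mm)

    def test_too_few_vertices(self, grid_1mm):
        with pytest.raises(ValueError, match="fewer than 3"):
            rasterize_contours([(1.0, np.array([[0.0, 0.0], [5.0, 5.0]]))], grid_1mm)


class TestSignedDistance:
    def test_immediate_exterior_face(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(2.5, 2.5, 2.5), shape=(7, 7, 7))
        m = np.zeros(grid.shape, dtype=bool)
        m[2:5, 2:5, 2:5] = True
        d = signed_distance_map(StructureMask("ptv", grid, m))
        assert d[5, 3, 3] == pytest.approx(2.5)
        assert d[4, 3, 3] == pytest.approx(-2.5)

    def test_sphere_center_depth(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(45, 45, 45))
        zz, yy, xx = np.indices(grid.shape)
        m = (zz - 22) ** 2 + (yy - 22) ** 2 + (xx - 22) ** 2 <= 20**2
        d = signed_distance_map(StructureMask("ptv", grid, m))
        assert d[22, 22, 22] == pytest.approx(-20.0, abs=1.0)

    def test_sign_convention(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 2, 3), shape=(8, 8, 8))
        rng = np.random.default_rng(3)
        m = np.zeros(grid.shape, dtype=bool)
        m[2:6, 1:5, 3:7] = rng.random((4, 4, 4)) < 0.7
        if not m.any() or m.all():
            m[3, 3, 3] = True
        d = signed_distance_map(StructureMask("ptv", grid, m))
        assert (d[m] < 0).all()
        assert (d[~m] > 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 12, size=3))
        spacing = tuple(rng.uniform(0.5, 3.0, size=3))
        m = rng.random(shape) < 0.3
        if not m.any():
            m[0, 0, 0] = True
        if m.all():
            m[0, 0, 0] = False
        grid = VoxelGrid(origin=(0, 0, 0), spacing=spacing, shape=shape)
        d = signed_distance_map(StructureMask("ptv", grid, m))
        np.testing.assert_allclose(d, brute_signed_distance(m, spacing), rtol=1e-12)

    def test_empty_ptv_rejected(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            signed_distance_map(StructureMask("ptv", grid, np.zeros(grid.shape, bool)))


class TestResample:
    def test_identity(self):
        grid = VoxelGrid(origin=(1, 2, 3), spacing=(2, 2, 2), shape=(5, 6, 7))
        arr = np.random.default_rng(0).random(grid.shape)
        out, n_out = resample_to_grid(arr, grid, grid, mode="trilinear")
        assert n_out == 0
        np.testing.assert_array_equal(out, arr)

    def test_constant_field(self):
        src = VoxelGrid(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(10, 10, 10))
        tgt = VoxelGrid(origin=(3, 3, 3), spacing=(1.5, 1.5, 1.5), shape=(8, 8, 8))
        out, n_out = resample_to_grid(np.full(src.shape, 7.5), src, tgt, "trilinear")
        assert n_out == 0
        np.testing.assert_allclose(out, 7.5)

    def test_linear_ramp_exact(self):
        src = VoxelGrid(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(10, 10, 12))
        ramp = np.broadcast_to(
            src.axis_coords(2) * 0.75, src.shape
        ).copy()
        tgt = VoxelGrid(origin=(2, 2, 2.7), spacing=(2, 2, 1.1), shape=(6, 6, 10))
        out, _ = resample_to_grid(ramp, src, tgt, "trilinear")
        np.testing.assert_allclose(out, np.broadcast_to(tgt.axis_coords(2) * 0.75, tgt.shape))

    def test_nearest_keeps_mask_binary(self):
        src = VoxelGrid(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(9, 9, 9))
        mask = np.random.default_rng(1).random(src.shape) < 0.5
        tgt = VoxelGrid(origin=(1, 1, 1), spacing=(1.3, 1.3, 1.3), shape=(9, 9, 9))
        out, _ = resample_to_grid(mask, src, tgt, "nearest")
        assert out.dtype == bool

    def test_out_of_extent_zeroed_and_counted(self):
        src = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(4, 4, 4))
        tgt = VoxelGrid(origin=(0, 0, 2), spacing=(1, 1, 1), shape=(4, 4, 4))
        out, n_out = resample_to_grid(np.ones(src.shape), src, tgt, "trilinear")
        assert n_out == 4 * 4 * 2
        assert out[:, :, -2:].sum() == 0

    def test_disjoint_extents_rejected(self):
        src = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(4, 4, 4))
        tgt = VoxelGrid(origin=(100, 100, 100), spacing=(1, 1, 1), shape=(4, 4, 4))
        with pytest.raises(ValueError, match="disjoint"):
            resample_to_grid(np.ones(src.shape), src, tgt, "trilinear")
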