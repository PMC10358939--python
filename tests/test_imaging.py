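import numpy as np
import pytest

from aggflow.imaging import (ImageStack, VoxelGrid, occupied_volume,
                             read_stack, resample_to_grid, smooth_geometry,
                             stack_and_interpolate, write_stack)


def disk_mask(n, radius_px, center=None):
    c = (n - 1) / 2 if center is None else center
    xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return ((xx - c) ** 2 + (yy - c) ** 2 <= radius_px ** 2).astype(np.uint8)


class TestImageStack:
    def test_mask_values_validated(self):
        with pytest.raises(ValueError):
            ImageStack(np.full((3, 3, 2), 2.0), (1e-3,) * 3, kind="mask")

    def test_spacing_validated(self):
        with pytest.raises(ValueError):
            ImageStack(np.zeros((3, 3, 2)), (1e-3, 0.0, 1e-3))

    def test_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.random((5, 7, 3)).astype(np.float32), (1e-3,) * 3)
        path = tmp_path / "s.tif"
        write_stack(stack, path)
        back = read_stack(path, stack.spacing)
        assert np.allclose(back.data, stack.data, atol=1e-7)


class TestStackAndInterpolate:
    def test_identical_disks_give_cylinder(self):
        m = disk_mask(21, 6)
        masks = ImageStack(np.repeat(m[:, :, None], 5, axis=2), (1e-3,) * 3,
                           kind="mask")
        occ = stack_and_interpolate(masks, 1e-3)
        hard = occ.data >= 0.5
        for k in range(hard.shape[2]):
            assert np.array_equal(hard[:, :, k], m.astype(bool))

    def test_cone_volume_within_two_percent(self):
        # disks shrinking linearly: a cone of base radius r and height h
        n, r_px, nz = 81, 30, 31
        dz = 1e-3
        slices = [disk_mask(n, r_px * (1 - k / (nz - 1))) for k in range(nz)]
        masks = ImageStack(np.stack(slices, axis=2), (1e-3, 1e-3, dz), kind="mask")
        occ = stack_and_interpolate(masks, dz / 4)
        vol = occupied_volume(occ)
        r = r_px * 1e-3
        h = (nz - 1) * dz
        exact = np.pi * r ** 2 * h / 3.0
        assert abs(vol - exact) / exact < 0.02

    def test_alternating_slices_half_occupancy_at_midplanes(self):
        full = np.ones((9, 9), dtype=np.uint8)
        empty = np.zeros((9, 9), dtype=np.uint8)
        masks = ImageStack(np.stack([empty, full, empty, full], axis=2),
                           (1e-3,) * 3, kind="mask")
        occ = stack_and_interpolate(masks, 0.5e-3)
        mid = occ.data[:, :, 1::2]  # planes halfway between the source slices
        assert np.allclose(mid, 0.5, atol=1e-9)

    def test_round_trip_at_native_resolution(self):
        rng = np.random.default_rng(5)
        data = (rng.random((15, 15, 6)) > 0.6).astype(np.uint8)
        masks = ImageStack(data, (1e-3,) * 3, kind="mask")
        occ = stack_and_interpolate(masks, 1e-3)
        assert np.array_equal(occ.data >= 0.5, data.astype(bool))

    def test_empty_stack_gives_empty_aggregate(self):
        masks = ImageStack(np.zeros((8, 8, 4), dtype=np.uint8), (1e-3,) * 3,
                           kind="mask")
        occ = stack_and_interpolate(masks, 1e-3)
        assert (occ.data == 0).all()

    def test_single_slice_extruded(self):
        m = disk_mask(15, 4)
        masks = ImageStack(m[:, :, None], (1e-3,) * 3, kind="mask")
        occ = stack_and_interpolate(masks, 1e-3)
        assert occ.shape[2] == 1
        assert np.array_equal(occ.data[:, :, 0] >= 0.5, m.astype(bool))

    def test_occupancy_bounded(self):
        rng = np.random.default_rng(9)
        data = (rng.random((12, 12, 5)) > 0.5).astype(np.uint8)
        occ = stack_and_interpolate(ImageStack(data, (1e-3,) * 3, kind="mask"),
                                    0.3e-3)
        assert occ.data.min() >= 0.0 and occ.data.max() <= 1.0


class TestSmoothGeometry:
    def _ball(self, n, r_px):
        c = (n - 1) / 2
        g = np.arange(n)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        occ = (((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) <= r_px ** 2)
        return ImageStack(occ.astype(float), (1e-3,) * 3, kind="occupancy")

    def test_zero_length_is_identity(self):
        stack = self._ball(21, 7)
        out = smooth_geometry(stack, 0.0)
        assert np.array_equal(out.data, stack.data)

    def test_large_sphere_volume_nearly_preserved(self):
        stack = self._ball(41, 16)
        out = smooth_geometry(stack, 1e-3)  # length << radius (16 voxels)
        v0 = occupied_volume(stack, soft=False)
        v1 = occupied_volume(out, soft=False)
        assert abs(v1 - v0) / v0 < 0.01

    def test_speck_removed(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = smooth_geometry(ImageStack(data, (1e-3,) * 3, kind="occupancy"),
                              5e-3)
        assert not (out.data >= 0.5).any()

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            smooth_geometry(self._ball(9, 3), -1e-3)


class TestResampleToGrid:
    def test_constant_preserved(self):
        stack = ImageStack(np.full((20, 20, 20), 3.7), (1e-3,) * 3)
        grid = VoxelGrid((8, 8, 8), 2e-3, origin=(1e-3, 1e-3, 1e-3))
        out = resample_to_grid(stack, grid)
        assert np.allclose(out, 3.7, atol=1e-12)

    def test_affine_field_reproduced(self):
        nx = 20
        x = np.arange(nx) * 1e-3
        f = (0.5 + 2.0 * x[:, None, None] + 3.0 * x[None, :, None]
             - 1.5 * x[None, None, :])
        stack = ImageStack(f, (1e-3,) * 3)
        grid = VoxelGrid((6, 6, 6), 2e-3, origin=(2e-3, 2e-3, 2e-3))
        out = resample_to_grid(stack, grid)
        xc = grid.cell_centers(0)
        expect = (0.5 + 2.0 * xc[:, None, None] + 3.0 * xc[None, :, None]
                  - 1.5 * xc[None, None, :])
        assert np.allclose(out, expect, atol=1e-12)

    def test_range_never_widens(self):
        rng = np.random.default_rng(2)
        stack = ImageStack(rng.random((16, 16, 16)), (1e-3,) * 3)
        grid = VoxelGrid((10, 10, 10), 1.3e-3, origin=(1e-3,) * 3)
        out = resample_to_grid(stack, grid)
        assert out.min() >= stack.data.min() - 1e-12 or out.min() >= 0.0
        assert out.max() <= stack.data.max() + 1e-12

    def test_down_up_sample_preserves_mean(self):
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(4)
        data = gaussian_filter(rng.random((32, 32, 32)), 3.0)
        stack = ImageStack(data, (1e-3,) * 3)
        coarse_grid = VoxelGrid((16, 16, 16), 2e-3, origin=(-0.5e-3,) * 3)
        coarse = resample_to_grid(stack, coarse_grid)
        coarse_stack = ImageStack(coarse, (2e-3,) * 3,
                                  origin=tuple(coarse_grid.cell_centers(a)[0]
                                               for a in range(3)))
        fine_grid = VoxelGrid((32, 32, 32), 1e-3, origin=(-0.5e-3,) * 3)
        fine = resample_to_grid(coarse_stack, fine_grid)
        inner = (slice(4, -4),) * 3  # away from the zero-padded border
        assert abs(fine[inner].mean() - data[inner].mean()) / data[inner].mean() < 0.01

    def test_no_overlap_warns_and_zeroes(self):
        stack = ImageStack(np.ones((4, 4, 4)), (1e-3,) * 3)
        grid = VoxelGrid((4, 4, 4), 1e-3, origin=(1.0, 1.0, 1.0))
        with pytest.warns(UserWarning):
            out = resample_to_grid(stack, grid)
        assert (out == 0).all()
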