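"""Low-level volume primitives against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenochip import volume_ops as vo

from oracles import (
    bfs_label,
    brute_erode6,
    brute_filter_size,
    brute_gaussian_kernel,
    brute_max_project,
    brute_reconstruct,
)


def masks(shape=(5, 12, 12)):
    return st.integers(0, 10_000).map(
        lambda s: np.random.default_rng(s).random(shape) < 0.35
    )


class TestGaussianLowpass:
    def test_kernel_matches_direct_construction(self):
        np.testing.assert_allclose(
            vo.gaussian_kernel_2d(10, 2.0), brute_gaussian_kernel(10, 2.0), atol=1e-12
        )
        assert vo.gaussian_kernel_2d(7, 1.5).sum() == pytest.approx(1.0)

    def test_preserves_constants(self):
        vol = np.full((3, 20, 20), 7.5)
        out = vo.gaussian_lowpass(vol, 10, 2)
        np.testing.assert_allclose(out, 7.5)

    def test_impulse_response_is_the_kernel(self):
        vol = np.zeros((1, 41, 41))
        vol[0, 20, 20] = 1.0
        out = vo.gaussian_lowpass(vol, 10, 2)
        # even-size kernel: response occupies the 10x10 window [16, 26)
        window = out[0, 16:26, 16:26]
        np.testing.assert_allclose(window, brute_gaussian_kernel(10, 2.0), atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_planes_filtered_independently(self):
        rng = np.random.default_rng(1)
        plane = rng.random((15, 15))
        vol = np.stack([plane, plane])
        out = vo.gaussian_lowpass(vol, 5, 1.2)
        np.testing.assert_allclose(out[0], out[1])

    @pytest.mark.parametrize("size,sigma", [(0, 1.0), (5, 0.0), (5, -2.0)])
    def test_invalid_parameters(self, size, sigma):
        with pytest.raises(ValueError):
            vo.gaussian_lowpass(np.zeros((1, 5, 5)), size, sigma)


class TestDifferenceOfGaussians:
    def test_constant_maps_to_zero(self):
        out = vo.difference_of_gaussians(np.full((2, 30, 30), 123.0), 10, 2, 60, 20)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_impulse_equals_kernel_difference(self):
        vol = np.zeros((1, 81, 81))
        vol[0, 40, 40] = 1.0
        out = vo.difference_of_gaussians(vol, 10, 2, 20, 6)
        assert out[0, 40, 40] > 0  # positive centre
        assert out.min() < 0       # negative surround
        fg = vo.gaussian_lowpass(vol, 10, 2)
        bg = vo.gaussian_lowpass(vol, 20, 6)
        np.testing.assert_allclose(out, fg - bg, atol=1e-12)

    def test_linearity_in_input(self, rng):
        vol = rng.random((2, 25, 25))
        out1 = vo.difference_of_gaussians(vol, 10, 2, 20, 6)
        out3 = vo.difference_of_gaussians(3.0 * vol, 10, 2, 20, 6)
        np.testing.assert_allclose(out3, 3.0 * out1, atol=1e-9)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            vo.difference_of_gaussians(np.zeros((1, 5, 5)), 10, 3, 10, 3)


class TestAverageFilter:
    def test_constant_and_identity(self):
        vol = np.full((2, 9, 9), 4.0)
        np.testing.assert_allclose(vo.average_filter(vol, 5), 4.0)
        rnd = np.random.default_rng(2).random((2, 9, 9))
        np.testing.assert_allclose(vo.average_filter(rnd, 1), rnd)

    def test_interior_impulse_spreads_to_window(self):
        vol = np.zeros((1, 11, 11))
        vol[0, 5, 5] = 25.0
        out = vo.average_filter(vol, 5)
        np.testing.assert_allclose(out[0, 3:8, 3:8], 1.0)
        assert out[0, 2, 5] == 0.0


class TestMaxProject:
    def test_matches_loop_oracle(self, rng):
        vol = rng.random((4, 10, 9))
        np.testing.assert_allclose(vo.max_project(vol), brute_max_project(vol))

    def test_dominated_plane_wins(self):
        a = np.zeros((7, 7))
        b = a + 5.0
        np.testing.assert_allclose(vo.max_project(np.stack([a, b])), b)


class TestFilterComponentsBySize:
    def test_boundary_semantics_inclusive(self):
        # a 4-voxel and a 5-voxel component; [5, 500] keeps only the latter
        mask = np.zeros((1, 5, 20), dtype=bool)
        mask[0, 0, :4] = True
        mask[0, 2, :5] = True
        out = vo.filter_components_by_size(mask, 5, 500)
        assert out[0, 2, :5].all() and not out[0, 0].any()

    def test_empty_mask(self):
        mask = np.zeros((2, 4, 4), dtype=bool)
        assert not vo.filter_components_by_size(mask, 1, 10).any()

    def test_min_greater_than_max_rejected(self):
        with pytest.raises(ValueError):
            vo.filter_components_by_size(np.zeros((2, 2, 2), bool), 10, 5)

    @settings(max_examples=30, deadline=None)
    @given(masks())
    def test_agrees_with_bfs_oracle_and_is_antiextensive(self, mask):
        out = vo.filter_components_by_size(mask, 3, 12)
        ref = brute_filter_size(mask, 3, 12)
        np.testing.assert_array_equal(out, ref)
        assert not (out & ~mask).any()


class TestErodeWithSurface:
    def test_cube_erodes_to_centre(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        eroded, surface = vo.erode_with_surface(mask)
        assert eroded.sum() == 1 and eroded[2, 2, 2]
        assert surface.sum() == 26

    def test_thin_sheet_fully_surface(self):
        mask = np.zeros((3, 6, 6), dtype=bool)
        mask[1] = True
        eroded, surface = vo.erode_with_surface(mask)
        assert not eroded.any()
        np.testing.assert_array_equal(surface, mask)

    @settings(max_examples=30, deadline=None)
    @given(masks())
    def test_partition_and_oracle(self, mask):
        eroded, surface = vo.erode_with_surface(mask)
        np.testing.assert_array_equal(eroded, brute_erode6(mask))
        assert not (eroded & surface).any()
        np.testing.assert_array_equal(eroded | surface, mask)


class TestReconstruct:
    def test_disjoint_seed_gives_empty(self):
        limit = np.zeros((1, 5, 5), dtype=bool)
        limit[0, :, :2] = True
        seed = np.zeros_like(limit)
        seed[0, 0, 4] = True
        assert not vo.reconstruct(seed, limit).any()

    def test_seed_equals_limit_is_identity(self, rng):
        limit = rng.random((3, 8, 8)) < 0.4
        np.testing.assert_array_equal(vo.reconstruct(limit, limit), limit)

    def test_selects_touched_component_only(self):
        limit = np.zeros((1, 3, 9), dtype=bool)
        limit[0, :, :3] = True
        limit[0, :, 6:] = True
        seed = np.zeros_like(limit)
        seed[0, 1, 1] = True
        out = vo.reconstruct(seed, limit)
        assert out[0, :, :3].all() and not out[0, :, 6:].any()

    @settings(max_examples=30, deadline=None)
    @given(masks(), masks())
    def test_oracle_and_idempotence(self, seed, limit):
        out = vo.reconstruct(seed, limit)
        np.testing.assert_array_equal(out, brute_reconstruct(seed, limit))
        np.testing.assert_array_equal(vo.reconstruct(out, limit), out)


class TestStitchMosaic:
    @staticmethod
    def _tiles_from(image, tile_w, overlap, shift=(0, 0)):
        """Cut a plane into two horizontally overlapping tiles; the second
        tile is taken `shift` px away from its nominal position."""
        h = image.shape[0]
        left = image[:, :tile_w]
        x0 = tile_w - overlap + shift[1]
        y0 = shift[0]
        right = np.zeros_like(left)
        src = image[max(0, y0) : min(h, h + y0), x0 : x0 + tile_w]
        oy = max(0, -y0)
        right[oy : oy + src.shape[0], : src.shape[1]] = src
        return [left, right]

    def test_single_field_unchanged(self, rng):
        field = rng.random((2, 10, 10))
        res = vo.stitch_mosaic([field], (1, 1), overlap=3)
        np.testing.assert_allclose(res.mosaic, field)

    @pytest.mark.parametrize("shift", [(0, 0), (3, -2), (-2, 3)])
    def test_recovers_known_integer_shift(self, shift):
        rng = np.random.default_rng(5)
        image = rng.random((60, 120)) * 100
        tiles = self._tiles_from(image, tile_w=70, overlap=20, shift=shift)
        res = vo.stitch_mosaic(tiles, (1, 2), overlap=20)
        dy = res.positions[1][0] - res.positions[0][0]
        dx = res.positions[1][1] - res.positions[0][1]
        assert (dy, dx) == (shift[0], 70 - 20 + shift[1])

    def test_shift_recovery_under_noise_within_one_px(self):
        rng = np.random.default_rng(6)
        image = rng.random((60, 120)) * 100
        tiles = self._tiles_from(image, tile_w=70, overlap=20, shift=(2, -1))
        tiles = [t + rng.normal(0, 10, t.shape) for t in tiles]
        res = vo.stitch_mosaic(tiles, (1, 2), overlap=20)
        dy = res.positions[1][0] - res.positions[0][0]
        dx = res.positions[1][1] - res.positions[0][1]
        assert abs(dy - 2) <= 1 and abs(dx - 49) <= 1

    def test_zero_variance_overlap_falls_back_to_nominal(self):
        tiles = [np.zeros((1, 20, 20)), np.zeros((1, 20, 20))]
        res = vo.stitch_mosaic(tiles, (1, 2), overlap=5)
        assert res.fallbacks == 1
        assert res.positions[1] == (0, 15)


@settings(max_examples=20, deadline=None)
@given(masks())
def test_bfs_oracle_agrees_with_ndimage_labelling(mask):
    """The test oracle itself is sane: same component count as scipy."""
    _, n_ref = bfs_label(mask)
    assert n_ref == vo.count_components(mask)
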