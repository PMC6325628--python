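"""Device (chip) segmentation: rough rules, refinement, phase guide, MC/PC."""

import numpy as np
import pytest

from phenochip.chip import (
    ChannelStack,
    ChipMasks,
    ChipNotFoundError,
    PhaseGuideError,
    derive_channels,
    detect_phaseguide,
    segment_chip_celldeath,
    segment_chip_mito,
    segment_chip_morphometric,
)
from phenochip.synthetic import FixtureSpec, chip_params_for, generate_chip_stack


def three_bars(heights=(30, 30, 30), xs=(10, 50, 90), w=8, shape=(40, 120)):
    mask = np.zeros(shape, dtype=bool)
    for h, x in zip(heights, xs):
        mask[:h, x : x + w] = True
    return mask


class TestDetectPhaseguide:
    def test_middle_block_by_x_order(self):
        mask = three_bars()
        pg = detect_phaseguide(mask)
        xs = np.flatnonzero(pg.any(axis=0))
        assert xs.min() == 50 and xs.max() == 57

    def test_two_blocks_is_an_error(self):
        mask = three_bars(heights=(30, 0, 30))
        with pytest.raises(PhaseGuideError, match="2"):
            detect_phaseguide(mask)

    def test_ordering_is_by_position_never_size(self):
        # middle-by-x block is the smallest: still the one returned
        mask = three_bars(heights=(40, 6, 40))
        pg = detect_phaseguide(mask)
        assert np.flatnonzero(pg.any(axis=0)).min() == 50
        assert pg.sum() == 6 * 8


class TestDeriveChannels:
    def test_left_right_split_of_complement(self):
        device = three_bars()
        device[:] = False
        device[:, 0:10] = True
        device[:, 55:65] = True
        device[:, 110:120] = True
        pg = np.zeros_like(device)
        pg[:, 55:65] = True
        mc, pc = derive_channels(pg, device)
        assert mc[:, 10:55].all() and not mc[:, 65:110].any()
        assert pc[:, 65:110].all() and not pc[:, 10:55].any()
        assert not (mc & pc).any()

    def test_flush_phaseguide_leaves_one_side_empty(self):
        device = np.zeros((10, 30), dtype=bool)
        device[:, 0:10] = True   # wall directly left of the guide
        device[:, 10:15] = True  # guide flush against it
        device[:, 25:] = True
        pg = np.zeros_like(device)
        pg[:, 10:15] = True
        mc, pc = derive_channels(pg, device)
        assert not mc.any()
        assert pc[:, 15:25].all()

    def test_channels_never_overlap_on_random_guides(self, rng):
        for _ in range(25):
            w = int(rng.integers(3, 10))
            x0 = int(rng.integers(12, 60))
            device = np.zeros((20, 90), dtype=bool)
            device[:, :8] = True
            device[:, 82:] = True
            device[:, x0 : x0 + w] = True
            pg = np.zeros_like(device)
            pg[:, x0 : x0 + w] = True
            mc, pc = derive_channels(pg, device)
            assert not (mc & pc).any()


class TestMorphometricChip:
    def test_fixture_walls_recovered_and_cells_excluded(self, morpho_fixture):
        spec, stack, gt, chip = morpho_fixture
        g = spec.geometry
        # device mask must cover the true wall/phase-guide footprints
        assert chip.device_2d[:, : g.wall_w].all()
        assert chip.device_2d[:, g.nx - g.wall_w :].all()
        assert chip.phaseguide_2d[:, g.pg_x0 : g.pg_x0 + g.pg_w].all()
        # every cellular object centre lies outside the 3D device mask
        for obj in gt.objects:
            assert not chip.device[g.nz // 2, int(obj["y"]), int(obj["x"])]

    def test_footprint_coverage(self, morpho_fixture):
        spec, stack, gt, chip = morpho_fixture
        union = chip.device_2d | chip.matrigel[0] | chip.perfusion[0]
        assert union.mean() >= 0.99

    def test_blank_stack_raises_chip_not_found(self):
        blank = ChannelStack({r: np.zeros((4, 64, 64)) for r in ("hoechst", "tuj1", "th", "stain4")})
        spec = FixtureSpec.morpho()
        with pytest.raises((ChipNotFoundError, RuntimeError)):
            segment_chip_morphometric(blank, chip_params_for(spec, "morpho"))

    def test_small_spurious_blob_removed(self, morpho_fixture):
        spec, _, _, _ = morpho_fixture
        stack, _ = generate_chip_stack(spec, "morpho")
        g = spec.geometry
        # a blob above the rough threshold but < min component size after
        # erosion must not survive into the device mask
        blob = np.zeros((g.ny, g.nx), dtype=bool)
        blob[100:125, 70:106] = True  # 900 px, shrinks further under erosion
        stack.channels["stain4"][:, blob] = 900.0
        chip = segment_chip_morphometric(stack, chip_params_for(spec, "morpho"))
        assert not chip.device_2d[112, 88]

    def test_deterministic_masks(self, morpho_fixture):
        spec, stack, _, chip = morpho_fixture
        chip2 = segment_chip_morphometric(stack, chip_params_for(spec, "morpho"))
        np.testing.assert_array_equal(chip.device, chip2.device)
        np.testing.assert_array_equal(chip.matrigel, chip2.matrigel)

    def test_phaseguide_confined_to_lowest_planes(self, morpho_fixture):
        *_, chip = morpho_fixture
        assert chip.phaseguide[:8].any()
        assert not chip.phaseguide[8:].any()


class TestMitoChipRule:
    @staticmethod
    def _rough_hit(tmrm, hoechst, mito):
        """Single-voxel truth-table probe of the rough rule via a flat patch."""
        shape = (1, 40, 40)
        stack = ChannelStack(
            {
                "tmrm": np.full(shape, float(tmrm)),
                "hoechst": np.full(shape, float(hoechst)),
                "mitotracker": np.full(shape, float(mito)),
                "cellmask": np.zeros(shape),
            }
        )
        from phenochip.chip import _avg_maxproj

        t = _avg_maxproj(stack["tmrm"])
        h = _avg_maxproj(stack["hoechst"])
        m = _avg_maxproj(stack["mitotracker"])
        rough = ((t > 10) & (t < 30)) | (((h > 30) & (h < 200)) & (m > 15))
        return bool(rough[20, 20])

    @pytest.mark.parametrize(
        "tmrm,hoechst,mito,expected",
        [
            (20, 0, 0, True),     # TMRM band alone
            (0, 100, 10, False),  # AND leg fails on MitoTracker
            (5, 100, 16, True),   # AND leg passes, TMRM band fails
            (30, 0, 0, False),    # strict upper bound
            (10, 0, 0, False),    # strict lower bound
            (0, 200, 50, False),  # strict Hoechst upper bound
        ],
    )
    def test_rule_truth_table(self, tmrm, hoechst, mito, expected):
        assert self._rough_hit(tmrm, hoechst, mito) is expected

    def test_fixture_walls_recovered(self, mito_fixture):
        spec, stack, gt, chip = mito_fixture
        g = spec.geometry
        assert chip.device_2d[:, : g.wall_w].all()
        for obj in gt.objects:
            assert not chip.device[g.nz // 2, int(round(obj["y"])), int(round(obj["x"]))]


class TestCellDeathChip:
    def test_rough_rule_bounds_are_strict(self):
        vol = np.zeros((1, 50, 50))
        vol[0, 10:40, 10:40] = 100.0
        vol[0, 20:30, 20:30] = 300.0
        from phenochip.chip import _avg_maxproj

        rough = (_avg_maxproj(vol) > 50) & (_avg_maxproj(vol) < 300)
        assert rough[15, 15]
        assert not rough[25, 25]

    def test_fixture_walls_recovered(self, viability_fixture):
        spec, stack, gt, chip = viability_fixture
        g = spec.geometry
        assert chip.device_2d[:, : g.wall_w].all()
        assert chip.device_2d[:, g.nx - g.wall_w :].all()
        for obj in gt.objects:
            assert not chip.device[g.nz // 2, int(round(obj["y"])), int(round(obj["x"]))]

    def test_blank_stack_raises(self):
        blank = ChannelStack({r: np.zeros((4, 64, 64)) for r in ("hoechst", "calcein", "eh", "cc3")})
        with pytest.raises((ChipNotFoundError, RuntimeError)):
            segment_chip_celldeath(blank)


def test_chipmasks_invariants_enforced():
    dev = np.zeros((2, 4, 4), dtype=bool)
    pg = np.zeros_like(dev)
    mc = np.zeros_like(dev)
    pc = np.zeros_like(dev)
    mc[0, 0, 0] = True
    pc[0, 0, 0] = True  # MC/PC overlap must be rejected
    with pytest.raises(ValueError):
        ChipMasks(dev, pg, mc, pc, dev[0], pg[0])
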