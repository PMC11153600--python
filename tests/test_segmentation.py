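import numpy as np
import pytest

from conftest import make_table
from oracles import density_oracle, point_in_mask_oracle
from palmcount import build_density_map, restrict_to_mask, segment
from palmcount.segmentation import mask_membership


class TestDensityMap:
    def test_no_emitters_all_zero(self):
        dmap = build_density_map((np.empty(0), np.empty(0)), 4.0, 4.0)
        assert dmap.values.shape == (200, 200)
        assert not dmap.values.any()

    def test_single_emitter_disk(self):
        dmap = build_density_map((np.array([2000.0]), np.array([2000.0])), 4.0, 4.0,
                                 pixel_size_nm=20.0)
        nonzero = dmap.values[dmap.values > 0]
        assert np.all(nonzero == 1)
        expected_pixels = np.pi * 500.0**2 / 20.0**2
        assert nonzero.size == pytest.approx(expected_pixels, rel=0.02)
        oracle = density_oracle([2000.0], [2000.0], 200, 200, 20.0)
        assert np.array_equal(dmap.values, oracle)

    def test_two_emitters_overlap_sums(self):
        x = np.array([1850.0, 2150.0])  # 300 nm apart
        y = np.array([2000.0, 2000.0])
        dmap = build_density_map((x, y), 4.0, 4.0, pixel_size_nm=20.0)
        oracle = density_oracle(x, y, 200, 200, 20.0)
        assert np.array_equal(dmap.values, oracle)
        assert (dmap.values == 2).any()
        # midpoint pixel is within 500 nm of both
        assert dmap.values[100, 100] == 2

    def test_random_scene_matches_bruteforce(self, rng):
        x = rng.uniform(0, 4000.0, 30)
        y = rng.uniform(0, 4000.0, 30)
        dmap = build_density_map((x, y), 4.0, 4.0, pixel_size_nm=50.0)
        oracle = density_oracle(x, y, 80, 80, 50.0)
        assert np.array_equal(dmap.values, oracle)

    def test_boundary_truncation(self):
        """Emitter at the corner: disk clipped, no wraparound."""
        dmap = build_density_map((np.array([0.0]), np.array([0.0])), 4.0, 4.0,
                                 pixel_size_nm=50.0)
        oracle = density_oracle([0.0], [0.0], 80, 80, 50.0)
        assert np.array_equal(dmap.values, oracle)
        assert dmap.values[-1, -1] == 0

    def test_adding_emitter_never_decreases(self, rng):
        x = rng.uniform(0, 4000.0, 10)
        y = rng.uniform(0, 4000.0, 10)
        base = build_density_map((x, y), 4.0, 4.0, pixel_size_nm=50.0)
        more = build_density_map(
            (np.append(x, 2000.0), np.append(y, 2000.0)), 4.0, 4.0, pixel_size_nm=50.0
        )
        assert np.all(more.values >= base.values)

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            build_density_map((np.empty(0), np.empty(0)), 4.0, 4.0, pixel_size_nm=0.0)


class TestSegment:
    def test_all_zero_map_empty_mask(self):
        dmap = build_density_map((np.empty(0), np.empty(0)), 4.0, 4.0)
        seg = segment(dmap)
        assert not seg.cell_mask.any()
        assert seg.area_um2 == 0.0

    def test_default_thresholds(self):
        dmap = build_density_map((np.array([2000.0]), np.array([2000.0])), 4.0, 4.0)
        seg = segment(dmap)
        assert (seg.lower, seg.upper) == (0.0, 150.0)
        # value-1 pixels are analysis area under (0, 150]
        assert seg.cell_mask.sum() == (dmap.values > 0).sum()

    def test_torch_cluster_excluded(self, rng):
        """200 emitters within 100 nm push the local density beyond 150."""
        x = rng.uniform(1950.0, 2050.0, 200)
        y = rng.uniform(1950.0, 2050.0, 200)
        dmap = build_density_map((x, y), 4.0, 4.0, pixel_size_nm=20.0)
        seg = segment(dmap)
        assert dmap.values[100, 100] >= 200
        assert seg.torch_mask[100, 100]
        assert not seg.cell_mask[100, 100]
        assert not (seg.cell_mask & seg.torch_mask).any()

    def test_whole_component_exclusion(self, rng):
        """The dim rim of a torch cluster is excluded in component mode."""
        x = rng.uniform(1950.0, 2050.0, 200)
        y = rng.uniform(1950.0, 2050.0, 200)
        dmap = build_density_map((x, y), 4.0, 4.0, pixel_size_nm=20.0)
        pixelwise = segment(dmap, whole_component=False)
        component = segment(dmap, whole_component=True)
        assert pixelwise.cell_mask.any()  # rim pixels below 150 survive
        assert not component.cell_mask.any()  # whole component removed
        assert component.torch_mask.sum() >= pixelwise.torch_mask.sum()

    def test_area_accounting(self, rng):
        x = rng.uniform(0, 4000.0, 50)
        y = rng.uniform(0, 4000.0, 50)
        dmap = build_density_map((x, y), 4.0, 4.0, pixel_size_nm=50.0)
        seg = segment(dmap, upper=3)
        px_um2 = 50.0**2 / 1e6
        assert seg.area_um2 == pytest.approx(seg.cell_mask.sum() * px_um2)
        assert seg.area_um2 + seg.torch_area_um2 <= 4.0 * 4.0 + 1e-9

    def test_bad_thresholds_rejected(self):
        dmap = build_density_map((np.empty(0), np.empty(0)), 1.0, 1.0)
        with pytest.raises(ValueError):
            segment(dmap, lower=150.0, upper=150.0)


class TestRestrictToMask:
    def test_full_mask_is_identity(self, rng):
        table = make_table([1, 2, 3], [100.0, 900.0, 500.0], [100.0, 900.0, 500.0])
        dmap = build_density_map((table.x, table.y), 1.0, 1.0, pixel_size_nm=50.0)
        seg = segment(dmap)
        seg.cell_mask[:] = True
        subset, report = restrict_to_mask(table, seg)
        assert len(subset) == 3
        assert report["n_kept"] == 3

    def test_pixel_boundary_floor_convention(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 2] = True
        inside, in_mask = mask_membership(
            np.array([100.0, 99.999]), np.array([100.0, 100.0]), mask, 50.0
        )
        # x = 100 is the boundary between pixels 1 and 2: floor assigns pixel 2
        assert in_mask[0]
        assert not in_mask[1]

    def test_outside_raster_counted(self):
        mask = np.ones((4, 4), dtype=bool)
        table = make_table([1, 2], [100.0, 1e6], [100.0, 100.0])
        dmap = build_density_map((np.array([100.0]), np.array([100.0])), 0.2, 0.2,
                                 pixel_size_nm=50.0)
        seg = segment(dmap)
        seg.cell_mask[:] = True
        subset, report = restrict_to_mask(table, seg)
        assert report["n_outside_raster"] == 1
        assert len(subset) == 1

    def test_matches_bruteforce_membership(self, rng):
        mask = rng.random((20, 20)) < 0.4
        x = rng.uniform(-100.0, 1100.0, 200)
        y = rng.uniform(-100.0, 1100.0, 200)
        inside, in_mask = mask_membership(x, y, mask, 50.0)
        assert np.array_equal(in_mask, point_in_mask_oracle(x, y, mask, 50.0))
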