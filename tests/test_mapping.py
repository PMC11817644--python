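"""CC mapping: RBF interpolation, region means, eye CCs, the CC table."""

import numpy as np
import pytest

from cathdose import synthetic
from cathdose.geometry import SliceGeometry, PhantomGrid, classify_region, region_mask
from cathdose.mapping import (
    CCTableRow,
    MappingError,
    assemble_cc_table,
    column_max,
    eye_cc,
    hull_mask,
    interpolate_grid,
    interpolate_slice,
    left_right_ratio,
    region_mean_cc,
)
from cathdose.reference import MEASURED_CC_TABLE
from cathdose.tld import PositionCC, PositionDose


def slice_sources(grid, slice_no, value_fn):
    """PositionCC list for one slice with cc = value_fn(x, y)."""
    index = grid.position_index()
    ccs, pixels = [], {}
    for pid, (sno, (x, y)) in index.items():
        if sno == slice_no:
            ccs.append(PositionCC(pid, float(value_fn(x, y)), slice_no=sno))
            pixels[pid] = (x, y)
    return ccs, pixels


class TestInterpolateSlice:
    def test_constant_sources_give_constant_raster(self, small_grid):
        geom = small_grid.slice_geometry(3)
        ccs, pixels = slice_sources(small_grid, 3, lambda x, y: 0.75)
        cc_map = interpolate_slice(ccs, geom, pixels)
        assert np.allclose(cc_map.in_mask_values(), 0.75, rtol=1e-9)

    def test_affine_field_reproduced_inside_hull(self, small_grid):
        """A thin-plate-spline interpolant reproduces an affine field
        a + bx + cy exactly (to 1e-6 relative) inside the source hull."""
        geom = small_grid.slice_geometry(3)
        affine = lambda x, y: 2.0 + 0.01 * x - 0.005 * y
        ccs, pixels = slice_sources(small_grid, 3, affine)
        cc_map = interpolate_slice(ccs, geom, pixels)
        hull = hull_mask(np.array(list(pixels.values())), geom.matrix_shape)
        sel = geom.brain_mask & hull
        yy, xx = np.nonzero(sel)
        expected = affine(xx, yy)
        assert np.allclose(cc_map.raster[yy, xx], expected, rtol=1e-6)

    def test_sources_reproduced_at_hole_pixels(self, small_grid, small_field):
        geom = small_grid.slice_geometry(4)
        ccs, pixels = slice_sources(
            small_grid, 4, lambda x, y: small_field.at(4, (x, y))
        )
        cc_map = interpolate_slice(ccs, geom, pixels)
        for pcc in ccs:
            x, y = pixels[pcc.position_id]
            assert cc_map.raster[y, x] == pytest.approx(pcc.cc, rel=1e-6)

    def test_exponential_field_recovered_within_hull(self, small_grid, small_field):
        geom = small_grid.slice_geometry(3)
        ccs, pixels = slice_sources(
            small_grid, 3, lambda x, y: small_field.at(3, (x, y))
        )
        cc_map = interpolate_slice(ccs, geom, pixels)
        hull = hull_mask(np.array(list(pixels.values())), geom.matrix_shape)
        sel = geom.brain_mask & hull
        yy, xx = np.nonzero(sel)
        truth = small_field.at_array(3, xx, yy)
        rel_err = np.abs(cc_map.raster[yy, xx] - truth) / truth
        assert rel_err.max() < 0.10

    def test_too_few_or_collinear_sources_raise(self, small_grid):
        geom = small_grid.slice_geometry(3)
        two = [PositionCC("a", 1.0, 3), PositionCC("b", 2.0, 3)]
        pixels = {"a": (60, 60), "b": (70, 60), "c": (80, 60)}
        with pytest.raises(MappingError, match=">= 3"):
            interpolate_slice(two, geom, pixels)
        collinear = two + [PositionCC("c", 3.0, 3)]
        with pytest.raises(MappingError, match="collinear"):
            interpolate_slice(collinear, geom, pixels)


@pytest.fixture(scope="module")
def maps(small_grid, small_field):
    ccs = []
    for geom in small_grid.slices:
        slice_ccs, _ = slice_sources(
            small_grid, geom.slice_no,
            lambda x, y, n=geom.slice_no: small_field.at(n, (x, y)),
        )
        ccs.extend(slice_ccs)
    return interpolate_grid(ccs, small_grid)


class TestRegionMeans:
    def test_constant_maps_give_constant_region_means(
        self, small_grid, small_thresholds
    ):
        ccs = []
        for geom in small_grid.slices:
            slice_ccs, _ = slice_sources(small_grid, geom.slice_no, lambda x, y: 0.5)
            ccs.extend(slice_ccs)
        maps = interpolate_grid(ccs, small_grid)
        for region in ("whole", "left", "right", "upper", "lower", "front", "rear"):
            assert region_mean_cc(
                maps, region, small_thresholds, small_grid
            ) == pytest.approx(0.5, rel=1e-9)

    def test_region_mean_matches_pixel_loop_oracle(
        self, maps, small_grid, small_thresholds
    ):
        """Independent oracle: loop over every mask pixel, classify it, and
        average the raster values per region."""
        sums = {r: 0.0 for r in ("left", "right", "front", "rear")}
        counts = {r: 0 for r in sums}
        for cc_map in maps:
            geom = small_grid.slice_geometry(cc_map.slice_no)
            yy, xx = np.nonzero(geom.brain_mask)
            for x, y in zip(xx, yy):
                labels = classify_region(
                    cc_map.slice_no, (x, y), small_thresholds, small_grid
                )
                for r in labels & sums.keys():
                    sums[r] += cc_map.raster[y, x]
                    counts[r] += 1
        for r in sums:
            oracle = sums[r] / counts[r]
            assert region_mean_cc(
                maps, r, small_thresholds, small_grid
            ) == pytest.approx(oracle, rel=1e-9)

    def test_whole_brain_is_pixel_weighted_combination_of_partitions(
        self, maps, small_grid, small_thresholds
    ):
        whole = region_mean_cc(maps, "whole", small_thresholds, small_grid)
        for a, b in (("upper", "lower"), ("left", "right"), ("front", "rear")):
            means, weights = [], []
            for r in (a, b):
                n = sum(
                    region_mask(
                        small_grid.slice_geometry(m.slice_no), r, small_thresholds
                    ).sum()
                    for m in maps
                )
                means.append(region_mean_cc(maps, r, small_thresholds, small_grid))
                weights.append(n)
            combined = np.average(means, weights=weights)
            assert whole == pytest.approx(combined, rel=1e-9)

    def test_left_skewed_field_orders_regions(self, maps, small_grid, small_thresholds):
        m = lambda r: region_mean_cc(maps, r, small_thresholds, small_grid)
        assert m("left") > m("right")
        assert m("front") > m("rear")

    def test_region_means_invariant_under_translation(self, small_grid, small_field):
        """Translating masks, holes and thresholds together leaves every
        region mean unchanged."""
        dx, dy = 7, 4
        moved_slices = []
        for geom in small_grid.slices:
            moved_slices.append(
                SliceGeometry(
                    slice_no=geom.slice_no,
                    brain_mask=np.roll(geom.brain_mask, (dy, dx), axis=(0, 1)),
                    hole_positions=[(x + dx, y + dy) for x, y in geom.hole_positions],
                )
            )
        moved = PhantomGrid(
            slices=tuple(moved_slices),
            eye_positions={
                k: (x + dx, y + dy) for k, (x, y) in small_grid.eye_positions.items()
            },
            pixel_spacing=small_grid.pixel_spacing,
            slice_thickness=small_grid.slice_thickness,
        )
        thr = synthetic.thresholds_for(small_grid)
        thr_moved = synthetic.thresholds_for(moved)

        def all_ccs(grid, value_at_original):
            out = []
            for geom in grid.slices:
                for i, (x, y) in enumerate(geom.hole_positions):
                    out.append(
                        PositionCC(
                            f"s{geom.slice_no}_h{i:02d}",
                            value_at_original(geom.slice_no, x, y),
                            geom.slice_no,
                        )
                    )
            return out

        base_maps = interpolate_grid(
            all_ccs(small_grid, lambda n, x, y: small_field.at(n, (x, y))), small_grid
        )
        moved_maps = interpolate_grid(
            all_ccs(moved, lambda n, x, y: small_field.at(n, (x - dx, y - dy))), moved
        )
        for region in ("whole", "left", "right", "front", "rear"):
            assert region_mean_cc(
                moved_maps, region, thr_moved, moved
            ) == pytest.approx(
                region_mean_cc(base_maps, region, thr, small_grid), rel=1e-9
            )

    def test_empty_region_raises(self, maps, small_grid, small_thresholds):
        from cathdose.geometry import RegionThresholds

        thr = RegionThresholds(
            upper_slices=frozenset({90, 91}),
            lower_slices=frozenset({2, 3, 4, 5}),
            left_min_x=small_thresholds.left_min_x,
            right_max_x=small_thresholds.right_max_x,
            front_max_y=small_thresholds.front_max_y,
            rear_min_y=small_thresholds.rear_min_y,
        )
        with pytest.raises(MappingError, match="no pixels"):
            region_mean_cc(maps, "upper", thr, small_grid)


class TestEyeCC:
    def test_eye_cc_is_dose_over_pka(self):
        left = PositionDose("left_eye", 1935.0, 0.0, False)
        right = PositionDose("right_eye", 890.0, 0.0, False)
        l, r = eye_cc(left, right, 500.0)
        assert l == pytest.approx(3.87)
        assert r == pytest.approx(1.78)

    def test_equal_doses_give_equal_ccs(self):
        d = PositionDose("left_eye", 100.0, 0.0, False)
        l, r = eye_cc(d, d, 400.0)
        assert l == r

    def test_zero_dose_gives_zero(self):
        z = PositionDose("left_eye", 0.0, 0.0, True)
        assert eye_cc(z, z, 400.0) == (0.0, 0.0)

    def test_missing_eye_raises(self):
        with pytest.raises(MappingError, match="both eye"):
            eye_cc(None, PositionDose("right_eye", 1.0, 0.0, False), 400.0)


class TestCCTable:
    def reference_rows(self):
        return [
            CCTableRow(configuration=name, **row.to_dict())
            for name, row in MEASURED_CC_TABLE.iterrows()
        ]

    def test_reference_table_column_max_and_ratios(self):
        table = assemble_cc_table(self.reference_rows())
        assert column_max(table)["left_eye"] == pytest.approx(5.47)
        ratios = left_right_ratio(table)
        assert round(ratios["brain"].max(), 1) == 2.0
        assert round(ratios["eye"].max(), 1) == 2.2

    def test_duplicate_labels_raise(self):
        rows = self.reference_rows()
        with pytest.raises(MappingError, match="duplicate"):
            assemble_cc_table(rows + rows[:1])

    def test_empty_input_gives_empty_table(self):
        assert assemble_cc_table([]).empty
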