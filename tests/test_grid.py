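"""Raster container, GeoTIFF round-trips, block aggregation, masking."""

import numpy as np
import pytest
import tifffile

from conftest import make_grid
from urbannature import (
    CityMask,
    Grid,
    GridAlignmentError,
    RasterIOError,
    block_aggregate,
    masked_cells,
    read_raster,
    write_raster,
)


class TestGridModel:
    def test_rejects_empty_or_1d_values(self):
        with pytest.raises(ValueError):
            Grid(np.zeros((0, 3)), cell_size=10.0)
        with pytest.raises(ValueError):
            Grid(np.zeros(5), cell_size=10.0)

    def test_rejects_nonpositive_cell_size(self):
        with pytest.raises(ValueError):
            Grid(np.zeros((2, 2)), cell_size=0.0)

    def test_rejects_nonfinite_cells_that_are_not_nodata(self):
        vals = np.array([[1.0, np.inf], [0.0, 2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            Grid(vals, cell_size=10.0)

    def test_nan_nodata_marks_invalid_cells(self):
        g = make_grid([[1.0, np.nan], [3.0, 4.0]], nodata=np.nan)
        assert g.invalid_mask().sum() == 1
        assert list(g.valid_values()) == [1.0, 3.0, 4.0]

    def test_alignment_same_lattice_shifted_origin(self):
        a = Grid(np.zeros((3, 3)), cell_size=10.0, origin=(0.0, 0.0))
        b = Grid(np.zeros((3, 3)), cell_size=10.0, origin=(20.0, -30.0))
        c = Grid(np.zeros((3, 3)), cell_size=10.0, origin=(5.0, 0.0))
        d = Grid(np.zeros((4, 3)), cell_size=10.0, origin=(0.0, 0.0))
        assert a.aligned_with(b)
        assert not a.aligned_with(c)
        assert not a.aligned_with(d)

    def test_mismatched_crs_tags_are_an_error(self):
        a = Grid(np.zeros((2, 2)), cell_size=10.0, crs_tag="EPSG:32618")
        b = Grid(np.zeros((2, 2)), cell_size=10.0, crs_tag="EPSG:32719")
        with pytest.raises(GridAlignmentError, match="CRS"):
            a.require_aligned(b)


class TestGeoTiffRoundTrip:
    def test_float_grid_round_trips_bit_identical(self, tmp_path):
        g = Grid(
            np.array([[0.25, -0.5, 1.0], [0.0, 0.125, -1.0], [0.7, 0.3, 0.9]]),
            cell_size=10.0,
            origin=(500000.0, 4300000.0),
            crs_tag="EPSG:32618",
        )
        path = tmp_path / "f.tif"
        write_raster(g, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, g.values)
        assert back.cell_size == g.cell_size
        assert back.origin == g.origin
        assert back.crs_tag == g.crs_tag
        assert back.nodata is None

    def test_categorical_grid_round_trips_codes(self, tmp_path):
        g = Grid(
            np.array([[10, 20], [80, 95]], dtype=np.int16),
            cell_size=10.0,
        )
        path = tmp_path / "c.tif"
        write_raster(g, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, g.values)
        assert back.values.dtype == np.int16

    def test_nodata_tag_propagates(self, tmp_path):
        vals = np.array([[1, 2], [255, 4]], dtype=np.uint8)
        g = Grid(vals, cell_size=10.0, nodata=255)
        path = tmp_path / "nd.tif"
        write_raster(g, path)
        back = read_raster(path)
        assert back.nodata == 255
        assert back.invalid_mask().sum() == 1

    def test_text_file_is_unreadable_raster(self, tmp_path):
        path = tmp_path / "not_a_raster.tif"
        path.write_text("hello")
        with pytest.raises(RasterIOError, match="unreadable raster"):
            read_raster(path)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(RasterIOError, match="no such raster"):
            read_raster(tmp_path / "absent.tif")

    def test_write_to_missing_directory_errors(self, tmp_path):
        g = make_grid([[1.0]])
        with pytest.raises(RasterIOError, match="directory does not exist"):
            write_raster(g, tmp_path / "nope" / "x.tif")

    def test_multiband_rejected(self, tmp_path):
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8),
                         photometric="rgb")
        with pytest.raises(RasterIOError, match="multi-band"):
            read_raster(path)

    def test_geographic_crs_rejected(self, tmp_path):
        path = tmp_path / "deg.tif"
        # GTModelType = 2 declares a geographic (degree) CRS
        geokeys = (1, 1, 0, 1, 1024, 0, 1, 2)
        tifffile.imwrite(
            path,
            np.zeros((3, 3), dtype=np.float32),
            extratags=[
                (33550, "d", 3, (0.0001, 0.0001, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, -77.0, 38.9, 0.0)),
                (34735, "H", len(geokeys), geokeys),
            ],
        )
        with pytest.raises(RasterIOError, match="geographic"):
            read_raster(path)


class TestBlockAggregate:
    def test_binary_block_mean_is_fraction_of_ones(self):
        vals = np.zeros((10, 10))
        vals.ravel()[:30] = 1.0
        coarse = block_aggregate(make_grid(vals), 10, "mean")
        assert coarse.shape == (1, 1)
        assert coarse.values[0, 0] == pytest.approx(0.30)
        assert coarse.cell_size == 100.0

    def test_all_nodata_block_stays_nodata(self):
        vals = np.full((10, 10), np.nan)
        coarse = block_aggregate(make_grid(vals, nodata=np.nan), 10, "mean")
        assert np.isnan(coarse.values[0, 0])

    def test_mean_over_valid_cells_only(self):
        vals = np.full((10, 10), np.nan)
        vals.ravel()[:50] = 0.0
        vals.ravel()[:20] = 1.0
        coarse = block_aggregate(make_grid(vals, nodata=np.nan), 10, "mean")
        assert coarse.values[0, 0] == pytest.approx(0.40)

    def test_partial_edge_blocks_use_existing_cells(self):
        vals = np.ones((12, 12))
        coarse = block_aggregate(make_grid(vals), 10, "mean")
        assert coarse.shape == (2, 2)
        np.testing.assert_allclose(coarse.values, 1.0)

    def test_max_reducer(self):
        vals = np.arange(16.0).reshape(4, 4)
        coarse = block_aggregate(make_grid(vals), 2, "max")
        np.testing.assert_array_equal(coarse.values, [[5.0, 7.0], [13.0, 15.0]])

    def test_mean_preserves_global_mean_without_nodata(self, rng):
        vals = rng.uniform(-1, 1, size=(40, 60))
        coarse = block_aggregate(make_grid(vals), 10, "mean")
        assert coarse.values.mean() == pytest.approx(vals.mean(), abs=1e-12)

    def test_output_bounded_by_input_range(self, rng):
        vals = rng.uniform(-3, 7, size=(30, 30))
        for reducer in ("mean", "max"):
            coarse = block_aggregate(make_grid(vals), 10, reducer)
            assert coarse.values.min() >= vals.min() - 1e-12
            assert coarse.values.max() <= vals.max() + 1e-12

    def test_invalid_factor_rejected(self):
        g = make_grid(np.ones((4, 4)))
        with pytest.raises(ValueError):
            block_aggregate(g, 0)
        with pytest.raises(ValueError):
            block_aggregate(g, -2)


class TestMaskedCells:
    def test_all_true_mask_returns_every_value(self):
        g = make_grid([[1.0, 2.0], [3.0, 4.0]])
        mask = CityMask(make_grid(np.ones((2, 2), dtype=np.uint8)))
        np.testing.assert_array_equal(masked_cells(g, mask), [1, 2, 3, 4])

    def test_nodata_cells_are_dropped_row_major(self):
        g = make_grid([[1.0, 2.0], [3.0, np.nan]], nodata=np.nan)
        mask = CityMask(make_grid(np.array([[1, 0], [1, 1]], dtype=np.uint8)))
        np.testing.assert_array_equal(masked_cells(g, mask), [1.0, 3.0])

    def test_mask_on_only_nodata_cells_gives_empty(self):
        g = make_grid([[np.nan, 2.0], [3.0, 4.0]], nodata=np.nan)
        mask = CityMask(make_grid(np.array([[1, 0], [0, 0]], dtype=np.uint8)))
        assert masked_cells(g, mask).size == 0

    def test_misaligned_inputs_rejected(self):
        g = make_grid(np.ones((2, 2)))
        mask = CityMask(make_grid(np.ones((3, 3), dtype=np.uint8)))
        with pytest.raises(GridAlignmentError):
            masked_cells(g, mask)

    def test_empty_city_mask_rejected(self):
        with pytest.raises(ValueError, match="no interior"):
            CityMask(make_grid(np.zeros((2, 2), dtype=np.uint8)))
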