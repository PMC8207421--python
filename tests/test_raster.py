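"""Elevation raster model, GeoTIFF I/O, alignment and boundary clipping."""

import numpy as np
import pytest
import shapely

from scrubmap import (Affine, BoundaryConfig, ConfigurationError, CoverageError,
                      CRSError, ElevationRaster, FormatError, align_to,
                      clip_to_boundary, read_elevation_raster,
                      write_elevation_raster)
from scrubmap.raster import require_projected

from conftest import CRS, make_raster


class TestElevationRaster:
    def test_invariants_rejected(self):
        t = Affine.from_origin(0, 1, 1, 1)
        with pytest.raises(ValueError):
            ElevationRaster(np.zeros((0, 3)), t, CRS)
        with pytest.raises(ValueError):
            ElevationRaster(np.zeros(4), t, CRS)
        with pytest.raises(ValueError):
            ElevationRaster(np.array([[np.inf]]), t, CRS)
        with pytest.raises(ValueError):
            ElevationRaster(np.zeros((2, 2)), Affine.from_origin(0, 1, 0.0, 1), CRS)

    def test_nan_and_sentinel_both_masked(self):
        r = make_raster([[1.0, np.nan], [-9999.0, 4.0]])
        assert r.mask.sum() == 2
        assert r.valid_area_m2 == 2.0

    def test_pixel_area(self, small_raster):
        assert small_raster.pixel_area == pytest.approx(0.25)
        assert small_raster.extent_area_m2 == pytest.approx(1.0)

    def test_geographic_crs_rejected_for_areas(self):
        r = make_raster([[1.0]], crs="EPSG:4326")
        with pytest.raises(CRSError):
            require_projected(r)
        require_projected(make_raster([[1.0]]))  # projected: fine


class TestGeoTiffRoundTrip:
    def test_values_transform_crs_nodata(self, small_raster, tmp_path):
        path = tmp_path / "r.tif"
        write_elevation_raster(small_raster, path)
        back = read_elevation_raster(path)
        assert np.array_equal(back.values, small_raster.values)
        assert back.transform == small_raster.transform
        assert back.crs == small_raster.crs
        assert back.nodata == small_raster.nodata
        assert back.pixel_area == pytest.approx(0.25)

    def test_mask_preserved(self, tmp_path):
        r = make_raster([[1.0, -9999.0], [3.0, 4.0]])
        path = tmp_path / "m.tif"
        write_elevation_raster(r, path)
        back = read_elevation_raster(path)
        assert back.mask.sum() == 1
        assert np.array_equal(back.mask, r.mask)

    def test_constant_mean_survives(self, flat_raster, tmp_path):
        path = tmp_path / "c.tif"
        write_elevation_raster(flat_raster, path)
        assert read_elevation_raster(path).valid_values.mean() == pytest.approx(7.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_elevation_raster(tmp_path / "absent.tif")

    def test_unreferenced_tiff_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((3, 3), dtype=np.float32))
        with pytest.raises(FormatError):
            read_elevation_raster(path)

    def test_multiband_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((3, 3, 3), dtype=np.uint8), photometric="rgb")
        with pytest.raises(FormatError):
            read_elevation_raster(path)


class TestAlignTo:
    @pytest.mark.parametrize("method", ["nearest", "bilinear"])
    def test_identity(self, small_raster, method):
        out = align_to(small_raster, small_raster, method)
        assert np.array_equal(out.values, small_raster.values)
        assert out.transform == small_raster.transform

    def test_constant_coarse_to_fine_nearest(self):
        coarse = make_raster(np.full((4, 4), 7.0), pixel=1.0)
        fine = make_raster(np.zeros((16, 16)), pixel=0.25)
        out = align_to(fine, coarse, "nearest")
        assert np.all(out.values == 7.0)

    def test_bilinear_hand_computed(self):
        # target [[0,2],[0,2]] at 1 m; centers at x=0.5 (value 0) and x=1.5 (value 2).
        # Reference centers at x=0.75 and 1.25 interpolate to 0.5 and 1.5; the
        # 0.25/1.75 columns need an out-of-extent stencil cell, hence nodata.
        tgt = make_raster([[0.0, 2.0], [0.0, 2.0]], pixel=1.0)
        ref = make_raster(np.zeros((4, 4)), pixel=0.5)
        out = align_to(ref, tgt, "bilinear")
        interior = out.values[1:3, 1:3]
        assert interior == pytest.approx(np.array([[0.5, 1.5], [0.5, 1.5]]))
        assert out.mask[:, 0].all() and out.mask[:, 3].all()

    def test_nodata_propagates_through_stencil(self):
        tgt = make_raster([[1.0, -9999.0], [1.0, 1.0]], pixel=1.0)
        ref = make_raster(np.zeros((4, 4)), pixel=0.5)
        out = align_to(ref, tgt, "bilinear")
        # every output pixel whose stencil touches the nodata corner is nodata
        assert out.mask[1, 2]

    def test_disjoint_extents(self):
        a = make_raster(np.zeros((2, 2)), origin=(0.0, 2.0))
        b = make_raster(np.zeros((2, 2)), origin=(100.0, 2.0))
        with pytest.raises(CoverageError):
            align_to(a, b, "nearest")

    def test_crs_mismatch(self):
        a = make_raster(np.zeros((2, 2)))
        b = make_raster(np.zeros((2, 2)), crs="EPSG:27700")
        with pytest.raises(CRSError):
            align_to(a, b, "nearest")


class TestClipToBoundary:
    def test_full_extent_is_identity(self, flat_raster, full_extent_boundary):
        out = clip_to_boundary(flat_raster, full_extent_boundary(flat_raster))
        assert np.array_equal(out.values, flat_raster.values)

    def test_exclude_left_half_halves_valid_area(self, flat_raster):
        west, south, east, north = flat_raster.bounds
        mid = (west + east) / 2
        b = BoundaryConfig(
            include_polygons=[shapely.box(west, south, east, north)],
            exclude_polygons=[shapely.box(west - 1, south - 1, mid, north + 1)],
        )
        out = clip_to_boundary(flat_raster, b)
        assert out.valid_mask.sum() == flat_raster.valid_mask.sum() / 2
        assert out.valid_area_m2 == pytest.approx(flat_raster.valid_area_m2 / 2)

    def test_include_outside_extent_warns_all_nodata(self, flat_raster):
        b = BoundaryConfig(include_polygons=[shapely.box(1000, 1000, 1010, 1010)])
        with pytest.warns(UserWarning):
            out = clip_to_boundary(flat_raster, b)
        assert out.mask.all()

    def test_empty_include_rejected(self, flat_raster):
        with pytest.raises(ConfigurationError):
            clip_to_boundary(flat_raster, BoundaryConfig())

    def test_area_bookkeeping(self, flat_raster):
        """valid_area(clipped) + masked-out pixel area == valid_area(original)."""
        west, south, east, north = flat_raster.bounds
        b = BoundaryConfig(include_polygons=[shapely.box(west, south, east - 1.3, north)])
        out = clip_to_boundary(flat_raster, b)
        masked_out = (out.mask & flat_raster.valid_mask).sum() * flat_raster.pixel_area
        assert out.valid_area_m2 + masked_out == pytest.approx(flat_raster.valid_area_m2)

    def test_never_increases_valid_pixels(self, flat_raster):
        b = BoundaryConfig(include_polygons=[shapely.box(0, 0, 3.1, 2.7)])
        out = clip_to_boundary(flat_raster, b)
        assert out.valid_mask.sum() <= flat_raster.valid_mask.sum()


class TestBoundaryConfig:
    def test_invalid_polygon_rejected(self):
        bowtie = shapely.Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ConfigurationError):
            BoundaryConfig(include_polygons=[bowtie])

    def test_geojson_round_trip(self, tmp_path):
        b = BoundaryConfig(
            include_polygons=[shapely.box(0, 0, 10, 10)],
            exclude_polygons=[shapely.box(2, 2, 4, 4)],
        )
        path = tmp_path / "b.geojson"
        b.to_geojson(path)
        back = BoundaryConfig.from_geojson(path)
        assert len(back.include_polygons) == 1
        assert len(back.exclude_polygons) == 1
        assert back.include_polygons[0].equals(b.include_polygons[0])
        assert back.exclude_polygons[0].equals(b.exclude_polygons[0])
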