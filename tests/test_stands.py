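"""Stand delineation: labeling vs a flood-fill oracle, exact polygonization."""

import numpy as np
import pytest

from scrubmap import (Affine, HeightBandScheme, band_area, classify_bands,
                      delineate_stands, label_components, polygonize,
                      stand_summary)
from scrubmap.errors import AlignmentError

from conftest import make_raster


def bands_from_heights(values, pixel=1.0):
    agm = make_raster(values, pixel=pixel)
    return agm, classify_bands(agm, HeightBandScheme.default())


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent brute-force oracle: BFS flood fill, numbered in scan order."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    out = np.zeros(mask.shape, dtype=int)
    nrows, ncols = mask.shape
    next_id = 0
    for r in range(nrows):
        for c in range(ncols):
            if mask[r, c] and out[r, c] == 0:
                next_id += 1
                queue = [(r, c)]
                out[r, c] = next_id
                while queue:
                    rr, cc = queue.pop()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < nrows and 0 <= nc < ncols
                                and mask[nr, nc] and out[nr, nc] == 0):
                            out[nr, nc] = next_id
                            queue.append((nr, nc))
    return out


class TestLabelComponents:
    def test_diagonal_touch_depends_on_connectivity(self):
        heights = np.zeros((4, 4))
        heights[0, 0] = heights[1, 1] = 3.0  # two scrub pixels touching diagonally
        _, bands = bands_from_heights(heights)
        assert label_components(bands, "scrub", connectivity=8).max() == 1
        assert label_components(bands, "scrub", connectivity=4).max() == 2

    def test_empty_and_full(self):
        _, empty = bands_from_heights(np.zeros((5, 5)))
        assert label_components(empty, "scrub", 8).max() == 0
        _, full = bands_from_heights(np.full((5, 5), 3.0))
        assert label_components(full, "scrub", 8).max() == 1

    def test_row_major_numbering(self):
        heights = np.zeros((5, 5))
        heights[4, 4] = 3.0  # placed "first" in value but last in scan order
        heights[0, 2] = 3.0
        heights[2, 0] = 3.0
        _, bands = bands_from_heights(heights)
        labeled = label_components(bands, "scrub", 4)
        assert labeled[0, 2] == 1 and labeled[2, 0] == 2 and labeled[4, 4] == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        """200 random rasters up to 30x30 agree exactly with the brute-force oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            shape = (int(rng.integers(1, 31)), int(rng.integers(1, 31)))
            mask = rng.random(shape) < rng.uniform(0.2, 0.8)
            _, bands = bands_from_heights(np.where(mask, 3.0, 0.0))
            ours = label_components(bands, "scrub", connectivity)
            oracle = flood_fill_label(mask, connectivity)
            assert np.array_equal(ours, oracle)


class TestPolygonize:
    transform = Affine.from_origin(0.0, 10.0, 0.25, 0.25)

    def test_single_pixel_square(self):
        labeled = np.zeros((4, 4), dtype=int)
        labeled[1, 2] = 1
        polys = polygonize(labeled, self.transform)
        assert polys[1].area == pytest.approx(0.0625)
        assert polys[1].bounds == (0.5, 9.5, 0.75, 9.75)

    def test_l_shape_hexagon(self):
        import shapely

        labeled = np.zeros((4, 4), dtype=int)
        labeled[1, 1] = labeled[2, 1] = labeled[2, 2] = 1
        polys = polygonize(labeled, self.transform)
        poly = polys[1]
        assert poly.area == pytest.approx(3 * 0.0625)
        # hand-enumerated hexagon vertices: pixel corners (col,row) mapped by
        # x = 0.25*col, y = 10 - 0.25*row
        expected = shapely.Polygon([
            (0.25, 9.75), (0.50, 9.75), (0.50, 9.50),
            (0.75, 9.50), (0.75, 9.25), (0.25, 9.25),
        ])
        assert poly.equals(expected)

    def test_ring_has_interior_hole(self):
        labeled = np.zeros((5, 5), dtype=int)
        labeled[1:4, 1:4] = 1
        labeled[2, 2] = 0
        polys = polygonize(labeled, self.transform)
        poly = polys[1]
        assert len(poly.interiors) == 1
        assert poly.area == pytest.approx(8 * 0.0625)

    def test_area_equals_pixel_count_random(self):
        rng = np.random.default_rng(5)
        mask = rng.random((20, 20)) < 0.5
        labeled = flood_fill_label(mask, 8)
        polys = polygonize(labeled, self.transform)
        for cid, poly in polys.items():
            n = (labeled == cid).sum()
            assert poly.area == pytest.approx(n * 0.0625, rel=1e-9)


class TestDelineateStands:
    def test_block_with_height_stats(self):
        heights = np.zeros((20, 20))
        heights[4:14, 4:14] = 3.0
        heights[8, 8] = 4.2
        agm, bands = bands_from_heights(heights, pixel=0.25)
        ss = delineate_stands(bands, agm, min_area_m2=0.5)
        assert len(ss) == 1
        stand = ss.stands[0]
        assert stand.area_m2 == pytest.approx(100 * 0.0625)
        assert stand.max_height_m == pytest.approx(4.2)
        assert stand.mean_height_m == pytest.approx((99 * 3.0 + 4.2) / 100)
        assert stand.polygon.area == pytest.approx(stand.area_m2, rel=1e-6)

    def test_single_tiny_pixel_dropped(self):
        heights = np.zeros((10, 10))
        heights[5, 5] = 3.0
        agm, bands = bands_from_heights(heights, pixel=0.05)  # 0.0025 m2 pixel
        ss = delineate_stands(bands, agm, min_area_m2=0.5)
        assert len(ss) == 0

    def test_min_area_threshold_inclusive(self):
        # three blocks of 0.4375, 0.5 and 2.0 m2 at 0.25 m pixels
        heights = np.zeros((20, 40))
        heights[1:8, 1:2] = 3.0     # 7 px = 0.4375 m2
        heights[1:9, 10:11] = 3.0   # 8 px = 0.5 m2 exactly
        heights[1:9, 20:24] = 3.0   # 32 px = 2.0 m2
        agm, bands = bands_from_heights(heights, pixel=0.25)
        ss = delineate_stands(bands, agm, min_area_m2=0.5)
        areas = sorted(s.area_m2 for s in ss)
        assert areas == pytest.approx([0.5, 2.0])

    def test_geometry_mismatch_rejected(self):
        agm, bands = bands_from_heights(np.zeros((5, 5)))
        other = make_raster(np.zeros((6, 6)))
        with pytest.raises(AlignmentError):
            delineate_stands(bands, other)

    def test_monotone_in_min_area(self):
        rng = np.random.default_rng(11)
        heights = np.where(rng.random((40, 40)) < 0.3, 3.0, 0.0)
        agm, bands = bands_from_heights(heights, pixel=0.5)
        prev_count, prev_total = np.inf, np.inf
        for min_area in [0.25, 0.5, 1.0, 2.0, 4.0]:
            ss = delineate_stands(bands, agm, min_area_m2=min_area)
            s = stand_summary(ss)
            assert s["count"] <= prev_count
            assert s["total_area_m2"] <= prev_total + 1e-9
            prev_count, prev_total = s["count"], s["total_area_m2"]

    def test_total_bounded_by_band_area(self):
        rng = np.random.default_rng(3)
        heights = np.where(rng.random((30, 30)) < 0.4, 3.0, 0.0)
        agm, bands = bands_from_heights(heights, pixel=0.5)
        scrub_area = band_area(bands, "scrub")
        ss_all = delineate_stands(bands, agm, min_area_m2=0.25)  # one pixel area
        assert ss_all.total_area_m2 == pytest.approx(scrub_area)
        ss_filtered = delineate_stands(bands, agm, min_area_m2=2.0)
        assert ss_filtered.total_area_m2 <= scrub_area


class TestStandSummary:
    def test_basic_and_empty(self):
        heights = np.zeros((30, 30))
        heights[1:3, 1:5] = 3.0    # 8 px = 2.0 m2 at 0.5 m
        heights[10:13, 10:14] = 3.0  # 12 px = 3.0 m2
        heights[20:25, 20:28] = 3.0  # 40 px = 10.0 m2
        agm, bands = bands_from_heights(heights, pixel=0.5)
        s = stand_summary(delineate_stands(bands, agm, min_area_m2=0.5))
        assert s == {"count": 3, "min_area_m2": 2.0, "max_area_m2": 10.0,
                     "total_area_m2": 15.0}
        empty = stand_summary(delineate_stands(bands, agm, min_area_m2=1e6))
        assert empty["count"] == 0 and empty["total_area_m2"] == 0.0

    def test_geojson_and_csv_export(self, tmp_path):
        import json

        heights = np.zeros((10, 10))
        heights[2:5, 2:5] = 3.0
        agm, bands = bands_from_heights(heights, pixel=0.5)
        ss = delineate_stands(bands, agm)
        gj = tmp_path / "stands.geojson"
        ss.to_geojson(gj)
        data = json.loads(gj.read_text())
        assert len(data["features"]) == 1
        props = data["features"][0]["properties"]
        assert props["area_m2"] == pytest.approx(9 * 0.25)
        csv_path = tmp_path / "stands.csv"
        ss.to_csv(csv_path)
        assert csv_path.read_text().startswith("id,area_m2")
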