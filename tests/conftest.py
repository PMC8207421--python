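import numpy as np
import pytest
import shapely

from scrubmap import Affine, BoundaryConfig, ElevationRaster

CRS = "EPSG:32630"


def make_raster(values, origin=(0.0, None), pixel=1.0, crs=CRS, nodata=-9999.0):
    """ElevationRaster from a 2-D array; origin defaults to (0, nrows*pixel)."""
    values = np.asarray(values, dtype=np.float32)
    west = origin[0]
    north = origin[1] if origin[1] is not None else values.shape[0] * pixel
    transform = Affine.from_origin(west, north, pixel, pixel)
    return ElevationRaster(values=values, transform=transform, crs=crs, nodata=nodata)


@pytest.fixture
def small_raster():
    return make_raster([[1.0, 2.0], [3.0, 4.0]], origin=(100.0, 200.0), pixel=0.5)


@pytest.fixture
def flat_raster():
    return make_raster(np.full((10, 10), 7.0), pixel=0.5)


@pytest.fixture
def full_extent_boundary():
    def _make(raster):
        west, south, east, north = raster.bounds
        return BoundaryConfig(include_polygons=[shapely.box(west, south, east, north)])

    return _make
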