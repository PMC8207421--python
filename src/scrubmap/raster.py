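"""Georeferenced elevation rasters: data model, GeoTIFF I/O, alignment, clipping.

The raster data model is deliberately small: a 2-D float32 grid of heights in
meters, an affine pixel-to-world transform, an EPSG coordinate reference
system, and a nodata sentinel. GeoTIFF files are read and written through
tifffile with the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory) and GDAL's nodata tag handled directly; the supported subset
is single-band, north-up, float32 imagery, which covers photogrammetric DSM
and DTM exports.

All area computations require a projected CRS in meter units. A geographic
(degree) CRS raises :class:`~scrubmap.errors.CRSError` rather than silently
producing wrong areas.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, CoverageError, CRSError, FormatError

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_CRS = 2048
_KEY_PROJECTED_CRS = 3072

_MODEL_PROJECTED = 1
_MODEL_GEOGRAPHIC = 2


@dataclass(frozen=True)
class Affine:
    """Affine pixel-to-world transform.

    Maps continuous pixel coordinates (col, row) — with (0, 0) the top-left
    corner of the top-left pixel — to world coordinates:

        x = a * col + b * row + c
        y = d * col + e * row + f
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        """North-up transform from the top-left corner and pixel sizes (m)."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def __call__(self, col, row):
        return (
            self.a * np.asarray(col) + self.b * np.asarray(row) + self.c,
            self.d * np.asarray(col) + self.e * np.asarray(row) + self.f,
        )

    def invert(self, x, y):
        """World coordinates back to continuous (col, row)."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("singular transform")
        dx = np.asarray(x) - self.c
        dy = np.asarray(y) - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (-self.d * dx + self.a * dy) / det
        return col, row

    @property
    def pixel_width(self) -> float:
        return math.hypot(self.a, self.d)

    @property
    def pixel_height(self) -> float:
        return math.hypot(self.b, self.e)

    @property
    def pixel_area(self) -> float:
        return abs(self.a * self.e - self.b * self.d)

    @property
    def is_north_up(self) -> bool:
        return self.b == 0.0 and self.d == 0.0 and self.a > 0 and self.e < 0


def is_geographic_crs(crs: str | None) -> bool:
    """Heuristic geographic-CRS check from the EPSG code.

    EPSG reserves the 4000–4999 block for 2-D geographic CRSs (4326, 4258,
    4269, ...). Without a full CRS database this range check is the practical
    test; projected systems used for survey work (UTM 32xxx, national grids)
    fall outside it.
    """
    if crs is None:
        return False
    code = _epsg_code(crs)
    return code is not None and 4000 <= code < 5000


def _epsg_code(crs: str) -> int | None:
    text = str(crs).upper()
    if text.startswith("EPSG:"):
        try:
            return int(text.split(":", 1)[1])
        except ValueError:
            return None
    return None


@dataclass
class ElevationRaster:
    """A georeferenced grid of elevations in meters.

    ``values`` holds float32 heights with ``nodata`` as the masked sentinel
    (NaN cells are always treated as nodata too). Used for the DSM, DTM and
    the above-ground model derived from them.
    """

    values: np.ndarray
    transform: Affine
    crs: str | None
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D grid, got ndim={self.values.ndim}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("grid must have at least one row and one column")
        pw, ph = self.transform.pixel_width, self.transform.pixel_height
        if not (pw > 0 and ph > 0 and math.isfinite(pw) and math.isfinite(ph)):
            raise ValueError("pixel width and height must be strictly positive and finite")
        if self.transform.pixel_area <= 0:
            raise ValueError("pixel area must be positive")
        valid = self.values[~self.mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("valid (non-nodata) values must be finite")

    # -- masking -----------------------------------------------------------

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the cell is nodata."""
        m = np.isnan(self.values)
        if not math.isnan(self.nodata):
            m |= self.values == np.float32(self.nodata)
        return m

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.mask

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area(self) -> float:
        return self.transform.pixel_area

    @property
    def valid_area_m2(self) -> float:
        return float(self.valid_mask.sum()) * self.pixel_area

    @property
    def extent_area_m2(self) -> float:
        return self.values.size * self.pixel_area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) of the full grid extent."""
        nrows, ncols = self.shape
        corners = np.array([[0, 0], [ncols, 0], [0, nrows], [ncols, nrows]], dtype=float)
        xs, ys = self.transform(corners[:, 0], corners[:, 1])
        return float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of every pixel center, each shaped like the grid."""
        nrows, ncols = self.shape
        cols, rows = np.meshgrid(np.arange(ncols) + 0.5, np.arange(nrows) + 0.5)
        return self.transform(cols, rows)

    def with_values(self, values: np.ndarray) -> "ElevationRaster":
        """Copy of this raster carrying new values on the same grid."""
        return replace(self, values=np.asarray(values, dtype=np.float32))

    def same_geometry(self, other: "ElevationRaster") -> bool:
        return self.shape == other.shape and self.transform == other.transform


def require_projected(raster_or_crs) -> None:
    """Raise CRSError unless the CRS is a projected (meter-unit) system."""
    crs = raster_or_crs.crs if hasattr(raster_or_crs, "crs") else raster_or_crs
    if crs is None:
        raise CRSError("a projected CRS is required for area computation; raster has none")
    if is_geographic_crs(crs):
        raise CRSError(
            f"CRS {crs} is geographic (degree units); area computation requires a "
            "projected CRS in meters"
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------


def _geokey_directory(crs: str) -> tuple[int, ...]:
    code = _epsg_code(crs)
    if code is None:
        raise FormatError(f"cannot encode CRS {crs!r}; an EPSG:<code> identifier is required")
    if is_geographic_crs(crs):
        keys = [(_KEY_MODEL_TYPE, 0, 1, _MODEL_GEOGRAPHIC), (_KEY_RASTER_TYPE, 0, 1, 1),
                (_KEY_GEOGRAPHIC_CRS, 0, 1, code)]
    else:
        keys = [(_KEY_MODEL_TYPE, 0, 1, _MODEL_PROJECTED), (_KEY_RASTER_TYPE, 0, 1, 1),
                (_KEY_PROJECTED_CRS, 0, 1, code)]
    out = [1, 1, 0, len(keys)]
    for k in keys:
        out.extend(k)
    return tuple(out)


def _parse_geokeys(directory) -> str | None:
    vals = list(directory)
    nkeys = vals[3]
    entries = {vals[4 + 4 * i]: vals[4 + 4 * i + 3] for i in range(nkeys)}
    if _KEY_PROJECTED_CRS in entries:
        return f"EPSG:{entries[_KEY_PROJECTED_CRS]}"
    if _KEY_GEOGRAPHIC_CRS in entries:
        return f"EPSG:{entries[_KEY_GEOGRAPHIC_CRS]}"
    return None


def write_elevation_raster(raster: ElevationRaster, path) -> None:
    """Write a single-band float32 GeoTIFF with georeferencing and nodata tags.

    Only north-up transforms are supported (the standard orientation of
    photogrammetric exports); round-trips losslessly through
    :func:`read_elevation_raster`.
    """
    t = raster.transform
    if not t.is_north_up:
        raise FormatError("only north-up (unrotated) transforms can be written to GeoTIFF")
    if raster.crs is None:
        raise FormatError("raster has no CRS; refusing to write an unreferenced GeoTIFF")
    values = raster.values.copy()
    values[raster.mask] = np.float32(raster.nodata)
    geokeys = _geokey_directory(raster.crs)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.a, -t.e, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(raster.nodata))),
    ]
    tifffile.imwrite(path, values, photometric="minisblack", extratags=extratags)


def read_elevation_raster(path) -> ElevationRaster:
    """Read a single-band GeoTIFF into an :class:`ElevationRaster`.

    Raises FileNotFoundError for a missing path, and
    :class:`~scrubmap.errors.FormatError` for multi-band or unreferenced
    files.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1 or len(tif.pages) != 1:
            raise FormatError(
                f"{path}: expected a single-band elevation GeoTIFF, got "
                f"{len(tif.pages)} page(s) with {page.samplesperpixel} sample(s) per pixel"
            )
        values = page.asarray()
        tags = page.tags
        scale_tag = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint_tag = tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tiepoint_tag is None:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        tie = tiepoint_tag.value
        i, j, _, x, y = (float(v) for v in tie[:5])
        transform = Affine.from_origin(x - sx * i, y + sy * j, sx, sy)
        geokeys = tags.get(_TAG_GEO_KEY_DIRECTORY)
        crs = _parse_geokeys(geokeys.value) if geokeys is not None else None
        if crs is None:
            raise FormatError(
                f"{path}: no coordinate reference system recorded; area computations "
                "require a projected CRS, so unreferenced rasters are rejected"
            )
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else float("nan")
    return ElevationRaster(values=values, transform=transform, crs=crs, nodata=nodata)


# ---------------------------------------------------------------------------
# Grid alignment
# ---------------------------------------------------------------------------


def _check_crs_match(a: ElevationRaster, b: ElevationRaster) -> None:
    if a.crs is not None and b.crs is not None and a.crs != b.crs:
        raise CRSError(
            f"CRS mismatch ({a.crs} vs {b.crs}); reprojection is not supported — "
            "provide rasters in a common projected CRS"
        )


def _check_overlap(a: ElevationRaster, b: ElevationRaster) -> None:
    aw, as_, ae, an = a.bounds
    bw, bs, be, bn = b.bounds
    if ae <= bw or be <= aw or an <= bs or bn <= as_:
        raise CoverageError("raster extents are disjoint; nothing to align")


def align_to(reference: ElevationRaster, target: ElevationRaster,
             method: str = "bilinear") -> ElevationRaster:
    """Resample ``target`` onto the exact grid of ``reference``.

    ``method`` is ``"bilinear"`` (default; appropriate for continuous
    elevation surfaces) or ``"nearest"``. Nodata is conservative: an output
    pixel is nodata if any input cell with nonzero interpolation weight is
    nodata or outside the target extent, so no heights are fabricated at
    data edges.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    _check_crs_match(reference, target)
    _check_overlap(reference, target)

    x, y = reference.pixel_centers()
    fcol, frow = target.transform.invert(x, y)
    nrows, ncols = target.shape
    tvalid = target.valid_mask
    tvals = target.values

    if method == "nearest":
        col = np.floor(fcol).astype(np.int64)
        row = np.floor(frow).astype(np.int64)
        inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        out = np.full(reference.shape, target.nodata, dtype=np.float32)
        cc, rr = col[inside], row[inside]
        ok = tvalid[rr, cc]
        vals = np.where(ok, tvals[rr, cc], np.float32(target.nodata))
        out[inside] = vals
    else:
        gc = fcol - 0.5
        gr = frow - 0.5
        c0 = np.floor(gc).astype(np.int64)
        r0 = np.floor(gr).astype(np.int64)
        tx = gc - c0
        ty = gr - r0
        out_vals = np.zeros(reference.shape, dtype=np.float64)
        bad = np.zeros(reference.shape, dtype=bool)
        for dc, dr, w in (
            (0, 0, (1 - tx) * (1 - ty)),
            (1, 0, tx * (1 - ty)),
            (0, 1, (1 - tx) * ty),
            (1, 1, tx * ty),
        ):
            cc = c0 + dc
            rr = r0 + dr
            inside = (cc >= 0) & (cc < ncols) & (rr >= 0) & (rr < nrows)
            ccs = np.clip(cc, 0, ncols - 1)
            rrs = np.clip(rr, 0, nrows - 1)
            valid = inside & tvalid[rrs, ccs]
            active = w > 0  # stencil cells actually touched
            bad |= active & ~valid
            out_vals += np.where(valid, w * tvals[rrs, ccs].astype(np.float64), 0.0)
        out = np.where(bad, np.float32(target.nodata), out_vals.astype(np.float32))

    return ElevationRaster(values=out, transform=reference.transform,
                           crs=reference.crs or target.crs, nodata=target.nodata)


# ---------------------------------------------------------------------------
# Boundary clipping
# ---------------------------------------------------------------------------


@dataclass
class BoundaryConfig:
    """Site boundary: include polygons minus exclude polygons (world meters)."""

    include_polygons: list[BaseGeometry] = field(default_factory=list)
    exclude_polygons: list[BaseGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for role, polys in (("include", self.include_polygons),
                            ("exclude", self.exclude_polygons)):
            for p in polys:
                if not p.is_valid or p.area <= 0:
                    raise ConfigurationError(
                        f"{role} polygon is invalid or has non-positive area"
                    )

    @classmethod
    def from_geojson(cls, path) -> "BoundaryConfig":
        """Load from a GeoJSON FeatureCollection.

        Features carrying ``"role": "exclude"`` in their properties are
        exclusion zones; everything else is part of the include boundary.
        """
        with open(path) as fh:
            data = json.load(fh)
        include, exclude = [], []
        if data.get("type") == "FeatureCollection":
            for feat in data["features"]:
                geom = shape(feat["geometry"])
                role = (feat.get("properties") or {}).get("role", "include")
                (exclude if role == "exclude" else include).append(geom)
        else:
            include.append(shape(data))
        return cls(include_polygons=include, exclude_polygons=exclude)

    def to_geojson(self, path) -> None:
        features = []
        for role, polys in (("include", self.include_polygons),
                            ("exclude", self.exclude_polygons)):
            for p in polys:
                features.append({"type": "Feature", "properties": {"role": role},
                                 "geometry": mapping(p)})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def boundary_mask(raster: ElevationRaster, boundary: BoundaryConfig) -> np.ndarray:
    """Boolean grid, True where the pixel center lies inside the boundary.

    Membership is decided by the pixel CENTER: inside (or on the edge of) at
    least one include polygon and not inside any exclude polygon.
    """
    if not boundary.include_polygons:
        raise ConfigurationError("boundary has no include polygons; nothing to clip to")
    x, y = raster.pixel_centers()
    include = shapely.union_all(boundary.include_polygons)
    shapely.prepare(include)
    keep = shapely.intersects_xy(include, x, y)
    if boundary.exclude_polygons:
        exclude = shapely.union_all(boundary.exclude_polygons)
        shapely.prepare(exclude)
        keep &= ~shapely.intersects_xy(exclude, x, y)
    return keep


def clip_to_boundary(raster: ElevationRaster, boundary: BoundaryConfig) -> ElevationRaster:
    """Mask every pixel whose center falls outside the boundary to nodata.

    Shape and transform are unchanged; only the nodata mask grows. If no
    pixel center is covered the result is all-nodata and a warning is issued.
    """
    keep = boundary_mask(raster, boundary)
    if not keep.any():
        warnings.warn("include polygons do not cover any pixel center; result is all nodata",
                      stacklevel=2)
    values = raster.values.copy()
    values[~keep] = np.float32(raster.nodata)
    return raster.with_values(values)
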