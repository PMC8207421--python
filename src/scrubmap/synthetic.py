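"""Synthetic DSM/DTM scene generation with analytic ground truth.

Every pipeline stage is testable without survey data: scenes combine a
smooth correlated random terrain, discrete canopy objects (ellipsoidal-cap
shrub and tree crowns, flat-topped buildings) and additive Gaussian surface
noise emulating photogrammetric reconstruction error. Each object carries
closed-form footprint areas, so recovery of stand counts and areas can be
checked against exact truth.

An ellipsoidal cap of peak height h over footprint semi-axes (a, b) exceeds
a height threshold t only over the concentric sub-ellipse of area
pi*a*b*(1 - (t/h)^2); recovery checks therefore compare against the analytic
area above the scrub band's lower bound — the detectable footprint — rather
than the full footprint, which no height-threshold method can see.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.affinity import scale as shapely_scale
from shapely.geometry import Point

from .errors import ConfigurationError
from .raster import Affine, BoundaryConfig, ElevationRaster

_DEFAULT_CRS = "EPSG:32630"  # any projected meter-unit system; UTM 30N

VALID_SHAPES = ("ellipsoidal_cap", "flat_top")
VALID_CLASSES = ("scrub", "tree", "building", "ruderal")


@dataclass(frozen=True)
class CanopySpec:
    """One above-ground object with an analytic footprint.

    ``ellipsoidal_cap``: height h at the center falling to 0 at the footprint
    ellipse (a smooth shrub/tree crown). ``flat_top``: constant height over an
    axis-aligned rectangle with half-extents ``semi_axes`` (a building).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    height: float
    shape: str = "ellipsoidal_cap"
    class_label: str = "scrub"

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ConfigurationError("semi_axes must be positive")
        if self.height <= 0:
            raise ConfigurationError("height must be positive")
        if self.shape not in VALID_SHAPES:
            raise ConfigurationError(f"shape must be one of {VALID_SHAPES}")
        if self.class_label not in VALID_CLASSES:
            raise ConfigurationError(f"class_label must be one of {VALID_CLASSES}")

    @property
    def footprint_area_m2(self) -> float:
        a, b = self.semi_axes
        if self.shape == "flat_top":
            return 4.0 * a * b  # full widths 2a x 2b
        return math.pi * a * b

    def area_above(self, threshold_m: float) -> float:
        """Analytic area (m²) where the canopy height field is ≥ threshold."""
        if threshold_m <= 0:
            return self.footprint_area_m2
        if threshold_m > self.height:
            return 0.0
        if self.shape == "flat_top":
            return self.footprint_area_m2
        frac = 1.0 - (threshold_m / self.height) ** 2
        return self.footprint_area_m2 * frac

    def footprint_polygon(self, threshold_m: float = 0.0, quad_segs: int = 128):
        """Shapely footprint of the region at or above ``threshold_m``."""
        cx, cy = self.center
        a, b = self.semi_axes
        if self.shape == "flat_top":
            if threshold_m > self.height:
                return shapely.Polygon()
            return shapely.box(cx - a, cy - b, cx + a, cy + b)
        if threshold_m > self.height:
            return shapely.Polygon()
        shrink = math.sqrt(max(0.0, 1.0 - (max(threshold_m, 0.0) / self.height) ** 2))
        circle = Point(cx, cy).buffer(1.0, quad_segs=quad_segs)
        return shapely_scale(circle, xfact=a * shrink, yfact=b * shrink,
                             origin=(cx, cy))

    def height_field(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Canopy height (m) at world coordinates; 0 outside the footprint."""
        cx, cy = self.center
        a, b = self.semi_axes
        if self.shape == "flat_top":
            inside = (np.abs(x - cx) <= a) & (np.abs(y - cy) <= b)
            return np.where(inside, self.height, 0.0)
        q = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2
        return self.height * np.sqrt(np.maximum(0.0, 1.0 - q))

    def to_row(self, cid: int) -> dict:
        return {
            "id": cid,
            "class": self.class_label,
            "shape": self.shape,
            "center_x": self.center[0],
            "center_y": self.center[1],
            "semi_axis_a": self.semi_axes[0],
            "semi_axis_b": self.semi_axes[1],
            "height_m": self.height,
            "footprint_area_m2": self.footprint_area_m2,
        }


@dataclass
class SyntheticScene:
    """A generated DSM/DTM pair with boundary and per-object truth."""

    dsm: ElevationRaster
    dtm: ElevationRaster
    boundary: BoundaryConfig
    truth: list[CanopySpec]
    seed: int
    noise_sd_m: float = 0.0
    config: dict = field(default_factory=dict)

    def canopies(self, class_label: str) -> list[CanopySpec]:
        return [c for c in self.truth if c.class_label == class_label]

    def merged_footprints(self, class_label: str, threshold_m: float = 0.0) -> list:
        """Union-merged footprints of one class at a height threshold.

        Overlapping same-class canopies merge into one footprint, because a
        height-based pipeline cannot separate touching crowns; recovery is
        defined against this merged truth.
        """
        geoms = [c.footprint_polygon(threshold_m) for c in self.canopies(class_label)]
        geoms = [g for g in geoms if not g.is_empty]
        if not geoms:
            return []
        merged = shapely.union_all(geoms)
        return list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]

    def analytic_area(self, class_label: str, threshold_m: float = 0.0) -> float:
        """Closed-form total area above a threshold, exact for disjoint canopies.

        Overlapping same-class canopies would be double-counted here; use
        ``merged_footprints`` areas (polygonal, discretized ellipses) when
        overlap matters.
        """
        return sum(c.area_above(threshold_m) for c in self.canopies(class_label))

    def export(self, directory) -> None:
        """Write dsm.tif, dtm.tif, boundary.geojson, truth.csv and config.json."""
        import csv

        from .raster import write_elevation_raster

        os.makedirs(directory, exist_ok=True)
        write_elevation_raster(self.dsm, os.path.join(directory, "dsm.tif"))
        write_elevation_raster(self.dtm, os.path.join(directory, "dtm.tif"))
        self.boundary.to_geojson(os.path.join(directory, "boundary.geojson"))
        with open(os.path.join(directory, "truth.csv"), "w", newline="") as fh:
            rows = [c.to_row(i + 1) for i, c in enumerate(self.truth)]
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else ["id"])
            writer.writeheader()
            writer.writerows(rows)
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump({"seed": self.seed, "noise_sd_m": self.noise_sd_m,
                       **self.config}, fh, indent=2)


def generate_terrain(extent_m: tuple[float, float], gsd_m: float,
                     relief_amplitude_m: float = 2.0,
                     correlation_length_m: float = 25.0,
                     base_elevation_m: float = 100.0,
                     seed: int = 0, crs: str = _DEFAULT_CRS) -> ElevationRaster:
    """Smooth undulating terrain: Gaussian-filtered white noise, band-limited.

    White noise is smoothed spectrally with a Gaussian of standard deviation
    ``correlation_length_m`` (periodic boundary), centered, and rescaled so
    max |elevation − base| equals ``relief_amplitude_m`` exactly. Reproducible
    under ``seed``.
    """
    width, height = extent_m
    if gsd_m <= 0:
        raise ConfigurationError("gsd_m must be positive")
    if gsd_m > min(width, height):
        raise ConfigurationError(
            f"ground sample distance {gsd_m} m exceeds the extent {extent_m}"
        )
    if relief_amplitude_m < 0:
        raise ConfigurationError("relief_amplitude_m must be >= 0")
    ncols = max(1, round(width / gsd_m))
    nrows = max(1, round(height / gsd_m))
    transform = Affine.from_origin(0.0, height, gsd_m, gsd_m)
    if relief_amplitude_m == 0:
        values = np.full((nrows, ncols), base_elevation_m, dtype=np.float32)
        return ElevationRaster(values=values, transform=transform, crs=crs)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nrows, ncols))
    sigma_px = correlation_length_m / gsd_m
    fy = np.fft.fftfreq(nrows)[:, None]
    fx = np.fft.rfftfreq(ncols)[None, :]
    kernel = np.exp(-2.0 * (math.pi * sigma_px) ** 2 * (fx**2 + fy**2))
    smooth = np.fft.irfft2(np.fft.rfft2(noise) * kernel, s=(nrows, ncols))
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth *= relief_amplitude_m / peak
    values = (base_elevation_m + smooth).astype(np.float32)
    return ElevationRaster(values=values, transform=transform, crs=crs)


def render_scene(dtm: ElevationRaster, canopies: list[CanopySpec],
                 noise_sd_m: float = 0.0, seed: int = 0,
                 boundary: BoundaryConfig | None = None,
                 config: dict | None = None) -> SyntheticScene:
    """DSM = DTM + max-over-canopies height field + Gaussian surface noise.

    Canopy fields combine by maximum (overlapping crowns shade each other,
    they do not stack). Noise is additive Gaussian on the DSM only; the DTM
    stays clean so recovery tests stay sharp against analytic truth.
    """
    west, south, east, north = dtm.bounds
    for c in canopies:
        cx, cy = c.center
        if not (west <= cx <= east and south <= cy <= north):
            raise ConfigurationError(
                f"canopy center {c.center} lies outside the terrain extent"
            )
    x, y = dtm.pixel_centers()
    canopy_field = np.zeros(dtm.shape, dtype=np.float64)
    for c in canopies:
        # evaluate only inside the canopy's bounding box of pixels
        cx, cy = c.center
        a, b = c.semi_axes
        col0, row0 = dtm.transform.invert(cx - a, cy + b)
        col1, row1 = dtm.transform.invert(cx + a, cy - b)
        r0 = max(0, int(np.floor(row0)))
        r1 = min(dtm.shape[0], int(np.ceil(row1)) + 1)
        c0 = max(0, int(np.floor(col0)))
        c1 = min(dtm.shape[1], int(np.ceil(col1)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        sub = c.height_field(x[r0:r1, c0:c1], y[r0:r1, c0:c1])
        np.maximum(canopy_field[r0:r1, c0:c1], sub, out=canopy_field[r0:r1, c0:c1])

    rng = np.random.default_rng(seed)
    dsm_vals = dtm.values.astype(np.float64) + canopy_field
    if noise_sd_m > 0:
        dsm_vals += rng.normal(0.0, noise_sd_m, size=dtm.shape)
    dsm_vals = dsm_vals.astype(np.float32)
    dsm_vals[dtm.mask] = np.float32(dtm.nodata)
    dsm = ElevationRaster(values=dsm_vals, transform=dtm.transform, crs=dtm.crs,
                          nodata=dtm.nodata)
    if boundary is None:
        boundary = BoundaryConfig(include_polygons=[shapely.box(west, south, east, north)])
    return SyntheticScene(dsm=dsm, dtm=dtm, boundary=boundary, truth=list(canopies),
                          seed=seed, noise_sd_m=noise_sd_m, config=config or {})


def preset_reserve(seed: int = 0) -> SyntheticScene:
    """A nature-reserve-like test scene with known truth.

    200 m x 200 m at 0.25 m ground sample distance: undulating grassland
    terrain, 30 mutually disjoint scrub canopies (peak heights 1.5-4.5 m), a
    block of 3 trees (>6 m) and one flat-topped building (4 m — inside the
    scrub height band, the classic confusion case), DSM noise sd 0.05 m. The
    site boundary excludes the tree block and the building compound, so the
    scrub pipeline should recover exactly the 30 scrub canopies.
    """
    extent = (200.0, 200.0)
    gsd = 0.25
    rng = np.random.default_rng(seed)
    terrain = generate_terrain(extent, gsd, relief_amplitude_m=3.0,
                               correlation_length_m=30.0, base_elevation_m=100.0,
                               seed=int(rng.integers(2**31)))

    canopies: list[CanopySpec] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)
    # scrub scattered over the grassland (south of the excluded blocks)
    while sum(c.class_label == "scrub" for c in canopies) < 30:
        a = float(rng.uniform(1.2, 3.0))
        b = float(rng.uniform(1.2, 3.0))
        h = float(rng.uniform(1.5, 4.5))
        r = max(a, b)
        cx = float(rng.uniform(6 + r, 194 - r))
        cy = float(rng.uniform(6 + r, 144 - r))
        if all(math.hypot(cx - px, cy - py) >= r + pr + 1.5 for px, py, pr in placed):
            canopies.append(CanopySpec((cx, cy), (a, b), h, "ellipsoidal_cap", "scrub"))
            placed.append((cx, cy, r))
    # tree block, north-west
    for _ in range(3):
        a = float(rng.uniform(3.0, 5.0))
        b = float(rng.uniform(3.0, 5.0))
        h = float(rng.uniform(6.5, 10.0))
        cx = float(rng.uniform(22, 60))
        cy = float(rng.uniform(162, 184))
        canopies.append(CanopySpec((cx, cy), (a, b), h, "ellipsoidal_cap", "tree"))
    # one building, north-east compound (flat top, 4 m: inside the scrub band)
    canopies.append(CanopySpec((170.0, 172.0), (4.0, 2.5), 4.0, "flat_top", "building"))

    boundary = BoundaryConfig(
        include_polygons=[shapely.box(0.0, 0.0, 200.0, 200.0)],
        exclude_polygons=[
            shapely.box(12.0, 152.0, 70.0, 194.0),   # tree block
            shapely.box(158.0, 162.0, 182.0, 182.0),  # building compound
        ],
    )
    scene = render_scene(terrain, canopies, noise_sd_m=0.05,
                         seed=int(rng.integers(2**31)), boundary=boundary,
                         config={"preset": "reserve", "extent_m": list(extent),
                                 "gsd_m": gsd})
    scene.seed = seed
    return scene
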