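"""Scrub stand delineation: connected components, polygonization, summaries.

A stand is one contiguous patch of scrub — the management unit. Stands are
the connected components of the scrub band (8-connectivity by default, since
diagonally touching canopies are one bush on the ground), filtered by a
minimum mapping unit (0.5 m² by default), and polygonized as exact
pixel-edge footprints so polygon areas agree with pixel counts to float
precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.affinity import affine_transform
from shapely.geometry import mapping

from .agm import BandRaster, check_same_geometry
from .errors import ConfigurationError
from .raster import Affine, ElevationRaster, require_projected

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class Stand:
    """One delineated scrub patch."""

    id: int
    polygon: shapely.geometry.base.BaseGeometry  # Polygon or MultiPolygon, world m
    area_m2: float
    max_height_m: float
    mean_height_m: float


@dataclass
class StandSet:
    """All stands from one delineation run, with the parameters that produced them."""

    stands: list[Stand]
    params: dict = field(default_factory=dict)
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.stands)

    def __iter__(self):
        return iter(self.stands)

    @property
    def total_area_m2(self) -> float:
        return float(sum(s.area_m2 for s in self.stands))

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {
                    "id": s.id,
                    "area_m2": s.area_m2,
                    "max_height_m": s.max_height_m,
                    "mean_height_m": s.mean_height_m,
                },
                "geometry": mapping(s.polygon),
            }
            for s in self.stands
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features,
                       "scrubmap:params": self.params, "scrubmap:crs": self.crs}, fh)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "area_m2", "max_height_m", "mean_height_m"])
            for s in self.stands:
                writer.writerow([s.id, f"{s.area_m2:.6f}",
                                 f"{s.max_height_m:.3f}", f"{s.mean_height_m:.3f}"])


def label_components(bands: BandRaster, label: str, connectivity: int = 8) -> np.ndarray:
    """Number the connected components of one band, 1..K; other cells 0.

    Numbering is deterministic: components are ordered by the row-major
    position of their first cell.
    """
    if connectivity not in _STRUCTURES:
        raise ConfigurationError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = bands.mask_for(label)
    labeled, k = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if k == 0:
        return labeled
    # Relabel to row-major first-encounter order (scipy's numbering is an
    # implementation detail we do not rely on).
    flat = labeled.ravel()
    ids, first = np.unique(flat, return_index=True)
    nz = ids != 0
    order = np.argsort(first[nz])
    remap = np.zeros(k + 1, dtype=labeled.dtype)
    remap[ids[nz][order]] = np.arange(1, k + 1)
    return remap[labeled]


def polygonize(labeled: np.ndarray, transform: Affine) -> dict[int, shapely.geometry.base.BaseGeometry]:
    """Exact pixel-edge footprint polygon for every component.

    Per-row pixel runs are unioned as integer-coordinate boxes in pixel
    space — an exact operation — then mapped to world coordinates, so each
    polygon's area equals pixel count × pixel area and enclosed non-member
    cells become interior rings. Components connected only diagonally
    (8-connectivity) come out as MultiPolygons.
    """
    out: dict[int, shapely.geometry.base.BaseGeometry] = {}
    ids = np.unique(labeled)
    ids = ids[ids != 0]
    # shapely affine_transform matrix [a, b, d, e, xoff, yoff] for (x y) = M (col row)
    matrix = [transform.a, transform.b, transform.d, transform.e, transform.c, transform.f]
    for cid in ids:
        rows, cols = np.nonzero(labeled == cid)
        boxes = []
        for r in np.unique(rows):
            cs = np.sort(cols[rows == r])
            breaks = np.nonzero(np.diff(cs) > 1)[0]
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(cs) - 1]))
            for s, e in zip(starts, ends):
                boxes.append(shapely.box(float(cs[s]), float(r), float(cs[e] + 1), float(r + 1)))
        geom = shapely.union_all(boxes)
        out[int(cid)] = affine_transform(geom, matrix)
    return out


def delineate_stands(bands: BandRaster, agm: ElevationRaster, label: str = "scrub",
                     min_area_m2: float = 0.5, connectivity: int = 8) -> StandSet:
    """Delineate stands of one band, dropping components below the minimum area.

    The minimum mapping unit test is inclusive (a component of exactly
    ``min_area_m2`` survives) and applies to whole-component area after
    labeling. Height statistics (max, mean) come from the AGM over each
    stand's member pixels. Stand ids are 1..K in row-major first-cell order.
    """
    if min_area_m2 <= 0:
        raise ConfigurationError(f"min_area_m2 must be positive, got {min_area_m2}")
    check_same_geometry(bands, agm)
    require_projected(agm)
    labeled = label_components(bands, label, connectivity)
    k = int(labeled.max())
    pixel_area = bands.pixel_area
    stands: list[Stand] = []
    if k > 0:
        counts = np.bincount(labeled.ravel(), minlength=k + 1)
        keep = [cid for cid in range(1, k + 1) if counts[cid] * pixel_area >= min_area_m2]
        kept = np.zeros(k + 1, dtype=labeled.dtype)
        kept[keep] = np.arange(1, len(keep) + 1)
        relabeled = kept[labeled]
        polygons = polygonize(relabeled, bands.transform)
        heights = agm.values.astype(np.float64)
        new_ids = np.arange(1, len(keep) + 1)
        sums = np.atleast_1d(ndimage.sum_labels(heights, relabeled, index=new_ids))
        maxs = np.atleast_1d(ndimage.maximum(heights, relabeled, index=new_ids))
        for new_id, old_id in enumerate(keep, start=1):
            n = int(counts[old_id])
            stands.append(Stand(
                id=new_id,
                polygon=polygons[new_id],
                area_m2=float(n * pixel_area),
                max_height_m=float(maxs[new_id - 1]),
                mean_height_m=float(sums[new_id - 1] / n),
            ))
    params = {"label": label, "min_area_m2": min_area_m2, "connectivity": connectivity,
              "pixel_area_m2": pixel_area}
    return StandSet(stands=stands, params=params, crs=bands.crs)


def stand_summary(stand_set: StandSet) -> dict:
    """Count, smallest/largest stand area and total area; zeros when empty."""
    areas = [s.area_m2 for s in stand_set.stands]
    if not areas:
        return {"count": 0, "min_area_m2": 0.0, "max_area_m2": 0.0, "total_area_m2": 0.0}
    return {
        "count": len(areas),
        "min_area_m2": float(min(areas)),
        "max_area_m2": float(max(areas)),
        "total_area_m2": float(sum(areas)),
    }
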