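"""Management products: site cover report, gridded cover map, removal plan.

These turn delineated stands into the numbers a reserve manager acts on.
Conservation prescriptions for priority grassland habitat are phrased as a
maximum percentage scrub cover (e.g. <5% for lowland calcareous grassland
under UK Common Standards Monitoring); the removal planner selects whole
stands until the residual cover meets such a prescription.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import mapping

from .agm import BandRaster
from .errors import ConfigurationError
from .raster import BoundaryConfig, boundary_mask, require_projected
from .stands import StandSet, stand_summary


@dataclass
class CoverReport:
    """Site-level scrub cover against the available habitat area."""

    available_area_m2: float
    scrub_area_m2: float
    cover_pct: float
    stand_count: int
    min_stand_area_m2: float
    max_stand_area_m2: float

    def to_dict(self) -> dict:
        return {
            "available_area_m2": self.available_area_m2,
            "scrub_area_m2": self.scrub_area_m2,
            "cover_pct": self.cover_pct,
            "stand_count": self.stand_count,
            "min_stand_area_m2": self.min_stand_area_m2,
            "max_stand_area_m2": self.max_stand_area_m2,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        # Full precision is kept internally; rounding happens only here.
        return (
            f"Available habitat: {self.available_area_m2:,.2f} m2\n"
            f"Scrub cover:       {self.scrub_area_m2:,.2f} m2 ({self.cover_pct:.2f}%)\n"
            f"Stands:            {self.stand_count} "
            f"(area range {self.min_stand_area_m2:,.2f}-{self.max_stand_area_m2:,.2f} m2)\n"
        )


def cover_report(stand_set: StandSet, available_area_m2: float) -> CoverReport:
    """Percentage scrub cover: 100 × total stand area / available habitat area."""
    if available_area_m2 <= 0:
        raise ConfigurationError(
            f"available area must be positive, got {available_area_m2}"
        )
    summary = stand_summary(stand_set)
    scrub = summary["total_area_m2"]
    return CoverReport(
        available_area_m2=float(available_area_m2),
        scrub_area_m2=scrub,
        cover_pct=100.0 * scrub / available_area_m2,
        stand_count=summary["count"],
        min_stand_area_m2=summary["min_area_m2"],
        max_stand_area_m2=summary["max_area_m2"],
    )


@dataclass
class GridCell:
    """One square assessment cell; ``cover_pct`` is None when no in-boundary area."""

    polygon: shapely.geometry.base.BaseGeometry
    in_boundary_area_m2: float
    scrub_area_m2: float
    cover_pct: float | None

    @property
    def empty(self) -> bool:
        return self.cover_pct is None


@dataclass
class GridCoverMap:
    """Per-cell scrub cover on a square grid anchored at the raster origin corner."""

    cell_side_m: float
    cells: list[GridCell]
    crs: str | None = None

    @property
    def total_scrub_area_m2(self) -> float:
        return float(sum(c.scrub_area_m2 for c in self.cells))

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {
                    "in_boundary_area_m2": c.in_boundary_area_m2,
                    "scrub_area_m2": c.scrub_area_m2,
                    "cover_pct": c.cover_pct,
                    "empty": c.empty,
                },
                "geometry": mapping(c.polygon),
            }
            for c in self.cells
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features,
                       "scrubmap:cell_side_m": self.cell_side_m,
                       "scrubmap:crs": self.crs}, fh)


def grid_cover(bands: BandRaster, boundary: BoundaryConfig, cell_side_m: float,
               label: str = "scrub") -> GridCoverMap:
    """Scrub cover per square grid cell, for within-site assessment.

    The grid is anchored at the raster's origin (top-left) corner. Each
    cell's denominator is its in-boundary valid-pixel area only, so a cell
    half outside the site that is fully scrub inside reads 100%. Cells with
    zero in-boundary area are flagged empty rather than reported as 0%.
    """
    t = bands.transform
    if cell_side_m <= 0 or cell_side_m < max(t.pixel_width, t.pixel_height):
        raise ConfigurationError(
            f"grid cell side {cell_side_m} m must be at least one pixel "
            f"({t.pixel_width} x {t.pixel_height} m)"
        )
    require_projected(bands)
    # Pixel-center membership, consistent with clip_to_boundary.
    helper = _RasterView(bands)
    inside = boundary_mask(helper, boundary) & bands.valid_mask
    scrub = bands.mask_for(label) & inside

    nrows, ncols = bands.shape
    cols, rows = np.meshgrid(np.arange(ncols) + 0.5, np.arange(nrows) + 0.5)
    x, y = t(cols, rows)
    x0, yN = t.c, t.f  # origin corner (west, north)
    ci = np.floor((x - x0) / cell_side_m).astype(np.int64)
    cj = np.floor((yN - y) / cell_side_m).astype(np.int64)  # rows count downward
    n_ci = int(ci.max()) + 1
    n_cj = int(cj.max()) + 1
    flat = cj * n_ci + ci
    pa = bands.pixel_area
    in_area = np.bincount(flat[inside], minlength=n_ci * n_cj) * pa
    scrub_area = np.bincount(flat[scrub], minlength=n_ci * n_cj) * pa

    cells: list[GridCell] = []
    for j in range(n_cj):
        for i in range(n_ci):
            a = float(in_area[j * n_ci + i])
            s = float(scrub_area[j * n_ci + i])
            poly = shapely.box(
                x0 + i * cell_side_m, yN - (j + 1) * cell_side_m,
                x0 + (i + 1) * cell_side_m, yN - j * cell_side_m,
            )
            cells.append(GridCell(
                polygon=poly,
                in_boundary_area_m2=a,
                scrub_area_m2=s,
                cover_pct=None if a == 0 else 100.0 * s / a,
            ))
    return GridCoverMap(cell_side_m=float(cell_side_m), cells=cells, crs=bands.crs)


class _RasterView:
    """Adapter giving a BandRaster the pixel-center interface boundary_mask needs."""

    def __init__(self, bands: BandRaster) -> None:
        self._bands = bands
        self.crs = bands.crs

    @property
    def shape(self):
        return self._bands.shape

    def pixel_centers(self):
        nrows, ncols = self._bands.shape
        cols, rows = np.meshgrid(np.arange(ncols) + 0.5, np.arange(nrows) + 0.5)
        return self._bands.transform(cols, rows)


@dataclass
class RemovalPlan:
    """Whole-stand removal schedule meeting a cover prescription."""

    target_pct: float
    available_area_m2: float
    allowed_area_m2: float
    stands_to_remove: list[int]
    removed_area_m2: float
    residual_cover_pct: float
    strategy: str = "largest_first"

    def to_csv(self, path, stand_set: StandSet | None = None) -> None:
        areas = {s.id: s.area_m2 for s in stand_set.stands} if stand_set else {}
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stand_id", "area_m2"])
            for sid in self.stands_to_remove:
                writer.writerow([sid, f"{areas.get(sid, float('nan')):.6f}"])

    def to_geojson(self, path, stand_set: StandSet) -> None:
        remove = set(self.stands_to_remove)
        features = [
            {
                "type": "Feature",
                "properties": {"id": s.id, "area_m2": s.area_m2,
                               "action": "remove" if s.id in remove else "keep"},
                "geometry": mapping(s.polygon),
            }
            for s in stand_set.stands
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features,
                       "scrubmap:target_pct": self.target_pct,
                       "scrubmap:strategy": self.strategy}, fh)

    def to_dict(self) -> dict:
        return {
            "target_pct": self.target_pct,
            "available_area_m2": self.available_area_m2,
            "allowed_area_m2": self.allowed_area_m2,
            "stands_to_remove": self.stands_to_remove,
            "removed_area_m2": self.removed_area_m2,
            "residual_cover_pct": self.residual_cover_pct,
            "strategy": self.strategy,
        }


def plan_removal(stand_set: StandSet, available_area_m2: float, target_pct: float,
                 strategy: str = "largest_first") -> RemovalPlan:
    """Greedy whole-stand removal until residual cover ≤ the prescription.

    ``largest_first`` (default) meets the target with the fewest
    interventions; ``smallest_first`` preserves the largest habitat blocks at
    the cost of more, smaller removals. Ties in area break by stand id. The
    plan is always feasible: removing every stand yields 0% cover. If the
    current cover already meets the target the plan is empty.
    """
    if not 0 <= target_pct <= 100:
        raise ConfigurationError(f"target_pct must be in [0, 100], got {target_pct}")
    if available_area_m2 <= 0:
        raise ConfigurationError(
            f"available area must be positive, got {available_area_m2}"
        )
    if strategy not in ("largest_first", "smallest_first"):
        raise ConfigurationError(f"unknown strategy {strategy!r}")

    allowed = target_pct / 100.0 * available_area_m2
    total = stand_set.total_area_m2
    reverse = strategy == "largest_first"
    order = sorted(stand_set.stands,
                   key=(lambda s: (-s.area_m2, s.id)) if reverse else (lambda s: (s.area_m2, s.id)))
    removed: list[int] = []
    removed_area = 0.0
    # Loop condition is in percentage space so the feasibility invariant
    # (residual_cover_pct <= target_pct) holds under the same comparison it
    # is stated in, with no one-ulp edge cases from the area/percent round trip.
    for stand in order:
        if 100.0 * (total - removed_area) / available_area_m2 <= target_pct:
            break
        removed.append(stand.id)
        removed_area += stand.area_m2
    residual = total - removed_area
    return RemovalPlan(
        target_pct=float(target_pct),
        available_area_m2=float(available_area_m2),
        allowed_area_m2=allowed,
        stands_to_remove=removed,
        removed_area_m2=removed_area,
        residual_cover_pct=100.0 * residual / available_area_m2,
        strategy=strategy,
    )
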