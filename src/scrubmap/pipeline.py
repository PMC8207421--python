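"""End-to-end pipeline: AGM → clip → classify → delineate → report (+ grid, plan).

The pipeline mirrors the field workflow for UAV-photogrammetry scrub surveys
after the elevation models exist: subtract terrain from surface, clip to the
site boundary, classify height bands, delineate stands, and produce the
management products. A machine-readable manifest recording every parameter
consumed, package version and input checksums accompanies the outputs so a
run can be re-created exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .agm import HeightBandScheme, classify_bands, compute_agm
from .errors import ConfigurationError
from .management import cover_report, grid_cover, plan_removal
from .raster import BoundaryConfig, clip_to_boundary, read_elevation_raster, write_elevation_raster
from .stands import delineate_stands

logger = logging.getLogger("scrubmap")


@dataclass
class RunConfig:
    """Everything one pipeline run consumes."""

    dsm_path: str
    dtm_path: str
    output_dir: str
    boundary_path: str | None = None
    scheme: str = "default"          # preset name or path to a YAML scheme
    min_area_m2: float = 0.5
    connectivity: int = 8
    clamp_negative: bool = True
    resampling: str = "bilinear"
    grid_cell_side_m: float | None = None
    target_pct: float | None = None
    strategy: str = "largest_first"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name, p in (("DSM", self.dsm_path), ("DTM", self.dtm_path),
                        ("boundary", self.boundary_path)):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.min_area_m2 <= 0:
            raise ConfigurationError("min_area_m2 must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if self.target_pct is not None and not 0 <= self.target_pct <= 100:
            raise ConfigurationError("target_pct must be in [0, 100]")
        if self.grid_cell_side_m is not None and self.grid_cell_side_m <= 0:
            raise ConfigurationError("grid_cell_side_m must be positive")


def load_scheme(name_or_path: str) -> HeightBandScheme:
    if os.path.exists(name_or_path):
        return HeightBandScheme.from_yaml(name_or_path)
    return HeightBandScheme.preset(name_or_path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all products to the output directory.

    Returns a dict with keys ``report``, ``stands``, and optionally ``grid``
    and ``plan``. Inputs are validated before any output is written so a bad
    config leaves no partial products.
    """
    config.validate()
    scheme = load_scheme(config.scheme)
    dsm = read_elevation_raster(config.dsm_path)
    dtm = read_elevation_raster(config.dtm_path)
    boundary = (BoundaryConfig.from_geojson(config.boundary_path)
                if config.boundary_path else None)

    out = config.output_dir
    os.makedirs(out, exist_ok=True)

    logger.info("computing AGM (%s resampling, clamp_negative=%s)",
                config.resampling, config.clamp_negative)
    agm = compute_agm(dsm, dtm, clamp_negative=config.clamp_negative,
                      method=config.resampling)
    if boundary is not None:
        logger.info("clipping to boundary (%d include, %d exclude polygons)",
                    len(boundary.include_polygons), len(boundary.exclude_polygons))
        agm = clip_to_boundary(agm, boundary)
    write_elevation_raster(agm, os.path.join(out, "agm.tif"))

    bands = classify_bands(agm, scheme)
    bands.export(os.path.join(out, "bands.tif"), os.path.join(out, "bands_legend.json"))

    stand_set = delineate_stands(bands, agm, label=scheme.scrub_label,
                                 min_area_m2=config.min_area_m2,
                                 connectivity=config.connectivity)
    logger.info("delineated %d stands totalling %.1f m2",
                len(stand_set), stand_set.total_area_m2)
    stand_set.to_geojson(os.path.join(out, "stands.geojson"))
    stand_set.to_csv(os.path.join(out, "stands.csv"))

    available = agm.valid_area_m2
    report = cover_report(stand_set, available)
    logger.info("scrub cover %.2f%% of %.1f m2 available habitat",
                report.cover_pct, available)
    report.to_json(os.path.join(out, "report.json"))
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(report.to_text())

    results = {"report": report, "stands": stand_set}

    if config.grid_cell_side_m is not None:
        grid_boundary = boundary or BoundaryConfig(
            include_polygons=[_extent_polygon(agm)])
        grid = grid_cover(bands, grid_boundary, config.grid_cell_side_m,
                          label=scheme.scrub_label)
        grid.to_geojson(os.path.join(out, "grid.geojson"))
        results["grid"] = grid

    if config.target_pct is not None:
        plan = plan_removal(stand_set, available, config.target_pct,
                            strategy=config.strategy)
        logger.info("removal plan: %d stands, %.1f m2, residual %.2f%% (target %.2f%%)",
                    len(plan.stands_to_remove), plan.removed_area_m2,
                    plan.residual_cover_pct, plan.target_pct)
        plan.to_geojson(os.path.join(out, "plan.geojson"), stand_set)
        plan.to_csv(os.path.join(out, "plan.csv"), stand_set)
        results["plan"] = plan

    manifest = {
        "scrubmap_version": __version__,
        "config": dataclasses.asdict(config),
        "scheme": scheme.to_dict(),
        "inputs": {
            "dsm": {"path": config.dsm_path, "sha256": _sha256(config.dsm_path)},
            "dtm": {"path": config.dtm_path, "sha256": _sha256(config.dtm_path)},
            **({"boundary": {"path": config.boundary_path,
                             "sha256": _sha256(config.boundary_path)}}
               if config.boundary_path else {}),
        },
        "results": {
            "available_area_m2": report.available_area_m2,
            "scrub_area_m2": report.scrub_area_m2,
            "cover_pct": report.cover_pct,
            "stand_count": report.stand_count,
            **({"removal_plan": results["plan"].to_dict()} if "plan" in results else {}),
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def _extent_polygon(raster):
    import shapely

    west, south, east, north = raster.bounds
    return shapely.box(west, south, east, north)
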