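"""Above-ground model (AGM) and height-band classification.

The AGM — elsewhere called a canopy height model — is the per-pixel height of
objects above ground, obtained by subtracting the bare-earth terrain model
(DTM) from the surface model (DSM). Classifying it into height bands
separates ground vegetation from scrub and from trees/structures: woody
shrub vegetation conventionally occupies roughly 1–5 m, between grassland
and woodland.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import AlignmentError, ClassificationError, ConfigurationError
from .raster import Affine, ElevationRaster, align_to

NODATA_INDEX = -1


@dataclass(frozen=True)
class HeightBand:
    """One labeled height interval [lower, upper) in meters."""

    label: str
    lower: float
    upper: float  # may be +inf

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"band {self.label!r}: lower bound {self.lower} must be < upper {self.upper}"
            )


@dataclass(frozen=True)
class HeightBandScheme:
    """Ordered, contiguous, non-overlapping height bands starting at 0 m.

    The interval convention is lower-inclusive / upper-exclusive, so every
    height belongs to exactly one band and band areas partition the valid
    raster area. Exactly one band is designated the scrub band. Values below
    0 (only possible when negative-height clamping is disabled) classify into
    the first band.
    """

    bands: tuple[HeightBand, ...]
    scrub_label: str = "scrub"
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("scheme must have at least one band")
        if self.bands[0].lower != 0:
            raise ConfigurationError("bands must be contiguous from 0 upward")
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if nxt.lower != prev.upper:
                raise ConfigurationError(
                    f"bands {prev.label!r} and {nxt.label!r} are not contiguous "
                    f"({prev.upper} != {nxt.lower})"
                )
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("band labels must be unique")
        if labels.count(self.scrub_label) != 1:
            raise ConfigurationError(
                f"exactly one band must carry the scrub label {self.scrub_label!r}"
            )

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    @property
    def scrub_band(self) -> HeightBand:
        return next(b for b in self.bands if b.label == self.scrub_label)

    # -- presets -------------------------------------------------------------

    @classmethod
    def default(cls) -> "HeightBandScheme":
        """Ground [0,1), scrub [1,5), tall [5,inf) — the conventional scrub definition."""
        return cls(
            bands=(
                HeightBand("ground", 0.0, 1.0),
                HeightBand("scrub", 1.0, 5.0),
                HeightBand("tall", 5.0, float("inf")),
            ),
            name="default",
        )

    @classmethod
    def daneway(cls) -> "HeightBandScheme":
        """Daneway Banks site calibration: scrub verified between 1.5 m and 5.75 m."""
        return cls(
            bands=(
                HeightBand("ground", 0.0, 1.5),
                HeightBand("scrub", 1.5, 5.75),
                HeightBand("tall", 5.75, float("inf")),
            ),
            name="daneway",
        )

    @classmethod
    def flatholm(cls) -> "HeightBandScheme":
        """Flat Holm island calibration: scrub between 1 m and 5 m."""
        return cls(
            bands=(
                HeightBand("ground", 0.0, 1.0),
                HeightBand("scrub", 1.0, 5.0),
                HeightBand("tall", 5.0, float("inf")),
            ),
            name="flatholm",
        )

    @classmethod
    def subbands(cls) -> "HeightBandScheme":
        """Splits scrub into low (1–3 m) and tall (3–5 m) management sub-bands.

        ``scrub_label`` points at the taller sub-band, the priority for
        intervention; pass ``scrub_label="low_scrub"`` to a custom scheme to
        target the other.
        """
        return cls(
            bands=(
                HeightBand("ground", 0.0, 1.0),
                HeightBand("low_scrub", 1.0, 3.0),
                HeightBand("tall_scrub", 3.0, 5.0),
                HeightBand("tall", 5.0, float("inf")),
            ),
            scrub_label="tall_scrub",
            name="subbands",
        )

    @classmethod
    def preset(cls, name: str) -> "HeightBandScheme":
        presets = {
            "default": cls.default,
            "daneway": cls.daneway,
            "flatholm": cls.flatholm,
            "subbands": cls.subbands,
        }
        if name not in presets:
            raise ConfigurationError(
                f"unknown scheme preset {name!r}; available: {sorted(presets)}"
            )
        return presets[name]()

    # -- config I/O ----------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "HeightBandScheme":
        bands = tuple(
            HeightBand(b["label"], float(b["lower"]),
                       float("inf") if b.get("upper") in (None, ".inf", "inf") else float(b["upper"]))
            for b in data["bands"]
        )
        return cls(bands=bands, scrub_label=data.get("scrub_label", "scrub"),
                   name=data.get("name", "custom"))

    @classmethod
    def from_yaml(cls, path) -> "HeightBandScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scrub_label": self.scrub_label,
            "bands": [
                {"label": b.label, "lower": b.lower,
                 "upper": None if b.upper == float("inf") else b.upper}
                for b in self.bands
            ],
        }


@dataclass
class BandRaster:
    """Grid of band indices with a legend, on the same geometry as its AGM."""

    labels: np.ndarray  # int16, NODATA_INDEX where masked
    legend: dict[int, str]
    transform: Affine
    crs: str | None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        present = np.unique(self.labels[self.labels != NODATA_INDEX])
        unknown = [int(i) for i in present if int(i) not in self.legend]
        if unknown:
            raise ValueError(f"band indices {unknown} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def pixel_area(self) -> float:
        return self.transform.pixel_area

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != NODATA_INDEX

    def index_of(self, label: str) -> int:
        for idx, lab in self.legend.items():
            if lab == label:
                return idx
        raise KeyError(f"label {label!r} not in legend {self.legend}")

    def mask_for(self, label: str) -> np.ndarray:
        return self.labels == self.index_of(label)

    def export(self, tif_path, legend_path=None) -> None:
        """Write the band indices as an integer GeoTIFF plus a JSON legend sidecar."""
        import tifffile

        from .raster import _geokey_directory  # shared tag encoding

        t = self.transform
        geokeys = _geokey_directory(self.crs)
        extratags = [
            (33550, "d", 3, (t.a, -t.e, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
            (34735, "H", len(geokeys), geokeys),
            (42113, "s", 0, str(NODATA_INDEX)),
        ]
        tifffile.imwrite(tif_path, self.labels, photometric="minisblack",
                         extratags=extratags)
        if legend_path is not None:
            with open(legend_path, "w") as fh:
                json.dump({str(k): v for k, v in self.legend.items()}, fh, indent=2)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_agm(dsm: ElevationRaster, dtm: ElevationRaster, clamp_negative: bool = True,
                method: str = "bilinear") -> ElevationRaster:
    """Above-ground model: DSM − DTM on the DSM grid.

    The DTM is resampled onto the DSM grid first (they commonly differ in
    resolution). Output is nodata wherever either input is. Negative
    differences — terrain model above the surface model, common sensor/
    reconstruction noise at data edges — are clamped to 0 by default so the
    AGM holds only positive above-ground heights; pass
    ``clamp_negative=False`` to inspect them.
    """
    dtm_on_dsm = dtm if dsm.same_geometry(dtm) else align_to(dsm, dtm, method=method)
    diff = dsm.values.astype(np.float64) - dtm_on_dsm.values.astype(np.float64)
    if clamp_negative:
        diff = np.maximum(diff, 0.0)
    invalid = dsm.mask | dtm_on_dsm.mask
    out = diff.astype(np.float32)
    out[invalid] = np.float32(dsm.nodata)
    return ElevationRaster(values=out, transform=dsm.transform, crs=dsm.crs,
                           nodata=dsm.nodata)


def classify_bands(agm: ElevationRaster, scheme: HeightBandScheme) -> BandRaster:
    """Assign every valid AGM cell to its height band.

    Each value lands in the unique band with lower ≤ value < upper; values
    below the first band's lower bound go to the first band. If the final
    band is bounded and any value reaches or exceeds its upper bound, a
    :class:`~scrubmap.errors.ClassificationError` reports the offending
    maximum — surfaces taller than the scheme anticipates (pylons,
    lighthouses) must be consciously handled, typically with an unbounded
    final band or an exclusion polygon.
    """
    uppers = np.array([b.upper for b in scheme.bands])
    valid = agm.valid_mask
    vals = agm.values[valid].astype(np.float64)
    idx = np.searchsorted(uppers, vals, side="right")
    if np.any(idx >= len(scheme.bands)):
        raise ClassificationError(
            f"AGM contains heights up to {vals.max():.2f} m, at or above the final "
            f"band's upper bound {uppers[-1]} m; use an unbounded final band or "
            "exclude the offending structures"
        )
    labels = np.full(agm.shape, NODATA_INDEX, dtype=np.int16)
    labels[valid] = idx.astype(np.int16)
    legend = {i: b.label for i, b in enumerate(scheme.bands)}
    return BandRaster(labels=labels, legend=legend, transform=agm.transform, crs=agm.crs)


def band_area(bands: BandRaster, label: str) -> float:
    """Total area (m²) of cells carrying ``label``: cell count × pixel area."""
    idx = bands.index_of(label)  # KeyError for unknown labels
    return float(np.count_nonzero(bands.labels == idx)) * bands.pixel_area


def check_same_geometry(bands: BandRaster, agm: ElevationRaster) -> None:
    if bands.shape != agm.shape or bands.transform != agm.transform:
        raise AlignmentError(
            "band raster and AGM do not share grid geometry "
            f"(shapes {bands.shape} vs {agm.shape})"
        )
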