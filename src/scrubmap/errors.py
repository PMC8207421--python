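"""Exception hierarchy for scrubmap.

All package errors derive from :class:`ScrubMapError` so callers can catch
one base class; specific subclasses mark the pipeline stage or contract that
failed.
"""


class ScrubMapError(Exception):
    """Base class for all scrubmap errors."""


class FormatError(ScrubMapError):
    """A file is not in the supported format (e.g. multi-band or CRS-less GeoTIFF)."""


class CRSError(ScrubMapError):
    """Coordinate reference systems are missing, mismatched, or not projected."""


class CoverageError(ScrubMapError):
    """Raster extents do not overlap where overlap is required."""


class ConfigurationError(ScrubMapError):
    """A configuration value is missing or out of its documented range."""


class ClassificationError(ScrubMapError):
    """Height values fall outside a bounded band scheme."""


class AlignmentError(ScrubMapError):
    """Two rasters expected to share a grid have different geometry."""
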