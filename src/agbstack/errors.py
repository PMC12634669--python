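"""Exception hierarchy shared by all pipeline stages."""


class AgbstackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AgbstackError):
    """Invalid configuration value, grid, or missing band/setting."""


class FormatError(AgbstackError):
    """Malformed input file (missing columns, empty table, bad dialect)."""


class DataError(AgbstackError):
    """Structurally valid input that cannot support the requested operation."""


class TemporalError(AgbstackError):
    """Survey years that do not define a positive elapsed interval."""


class GeometryError(AgbstackError):
    """Footprint/raster geometry mismatch (outside extent, CRS conflict)."""


class SchemaError(AgbstackError):
    """A required feature or column is absent at prediction time."""


class DensityLookupError(AgbstackError):
    """Species has no wood-density entry and no group fallback applies."""


class SummaryError(AgbstackError):
    """Summary requested over an empty/all-nodata domain."""
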