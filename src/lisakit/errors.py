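"""Exception hierarchy for lisakit.

All data / configuration problems raise a subclass of :class:`LisaError`,
so callers (and the CLI) can distinguish them from programming errors.
"""


class LisaError(Exception):
    """Base class for all lisakit data and configuration errors."""


class DataFormatError(LisaError):
    """Malformed input file (GeoJSON / CSV)."""


class DuplicateIdError(DataFormatError):
    """Duplicate area identifier or duplicate (area, time) record."""


class UnsupportedGeometryError(DataFormatError):
    """Feature geometry is not a Polygon or MultiPolygon."""


class JoinError(LisaError):
    """Value table references areas absent from the geometry collection."""


class DegenerateInputError(LisaError):
    """Input on which a statistic is undefined (e.g. constant values)."""


class WeightError(LisaError):
    """Weight matrix used with the wrong flags or dimensions."""


class InferenceFailureError(LisaError):
    """Permutation inference could not produce a usable null distribution."""


class ConfigError(LisaError):
    """Invalid run configuration."""
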