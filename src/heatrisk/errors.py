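"""Exception hierarchy shared by all heatrisk modules.

Two broad families matter to callers: validation problems (bad inputs,
bad configuration -> CLI exit code 2) and degenerate-data problems
(inputs that parse but cannot support the computation -> exit code 3).
"""


class HeatriskError(Exception):
    """Base class for all package errors."""


class ValidationError(HeatriskError):
    """Malformed or out-of-contract input (bad CSV row, duplicate ids...)."""

    exit_code = 2


class InvalidGeometryError(ValidationError):
    """Polygon with < 3 distinct vertices, zero-area zone, etc."""


class ConfigurationError(ValidationError):
    """Bad weights, unknown class label, k larger than distinct values..."""


class DegenerateDataError(HeatriskError):
    """Data parsed fine but the computation is undefined on it."""

    exit_code = 3


class DegenerateLayerError(DegenerateDataError):
    """A layer with no positive value cannot be standardized."""


class EmptyRasterError(DegenerateDataError):
    """Raster contains no non-nodata cell."""


class CoverageError(DegenerateDataError):
    """Raster and zones do not overlap in extent."""


class UndefinedCorrelationError(DegenerateDataError):
    """Spearman correlation against a constant vector."""
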