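"""Exception hierarchy shared across the pipeline stages.

The CLI maps these onto exit codes: configuration problems -> 2,
data/geometry problems -> 3, numerical failures -> 4.
"""


class BlurbenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BlurbenchError):
    """Invalid configuration or parameter value."""


class DataError(BlurbenchError):
    """Missing, unreadable or malformed input data."""


class GeometryError(DataError):
    """Window / margin / mosaic geometry that cannot be satisfied."""


class NumericError(BlurbenchError):
    """A numerical procedure failed outright (not a mere warning)."""
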