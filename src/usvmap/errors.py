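"""Exception hierarchy shared across the pipeline.

Config problems (bad geometry, unresolvable dialects) and data problems
(malformed tables, too few rows) are kept distinct so the command-line
driver can map them to different exit codes.
"""


class UsvMapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(UsvMapError):
    """Invalid or inconsistent configuration (geometry, dialect, run config)."""


class DataError(UsvMapError):
    """Invalid input data."""


class FormatError(DataError):
    """A table could not be parsed: missing column, unit mismatch, bad value."""


class InsufficientDataError(DataError):
    """Fewer valid rows than the operation requires."""
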