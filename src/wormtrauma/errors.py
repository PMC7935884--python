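"""Exception hierarchy.

Configuration problems (bad parameters, impossible simulation settings) are
distinguished from data problems (malformed tables, degenerate inputs) so the
command-line layer can map them to distinct exit codes.
"""


class WormtraumaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WormtraumaError, ValueError):
    """Invalid parameter values or inconsistent configuration."""


class DataError(WormtraumaError, ValueError):
    """Malformed, empty, or degenerate input data."""


class SchemaError(DataError):
    """A table is missing required columns or holds non-numeric values."""


class DegenerateControlError(DataError):
    """The empty-vector control shows no fluorescence loss, so the
    normalized index is undefined."""
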