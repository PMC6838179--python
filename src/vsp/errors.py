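"""Exception hierarchy shared across the package."""


class VspError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VspError):
    """A required column or field is missing from an input table."""


class TableParseError(VspError):
    """A cell in an input table could not be parsed; carries the row number."""


class ConfigError(VspError):
    """Inconsistent or incomplete run configuration."""


class InsufficientDataError(VspError):
    """Too few observations for the requested operation."""


class EmptyVariogramError(VspError):
    """No variant pair falls inside the active lag distance."""


class SingularSystemError(VspError):
    """The kriging system is singular (typically coincident observations)."""


class GridMismatchError(VspError):
    """Two landscapes do not share the same grid or axis meaning."""
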