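class QuitcostError(Exception):
    """Base class for all package errors."""


class ValidationError(QuitcostError, ValueError):
    """A field or argument value violates its contract."""


class ConfigurationError(QuitcostError, ValueError):
    """The run configuration is incomplete or inconsistent (bad column map,
    missing file, malformed cost table)."""
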