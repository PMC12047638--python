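"""Exception types shared across the package."""


class SharedrepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SharedrepError, ValueError):
    """Invalid parameters, design counts, or run configuration."""


class DataError(SharedrepError, ValueError):
    """Malformed or inconsistent input data (tables, volumes, features)."""
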