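"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class PlexquantError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PlexquantError):
    """Invalid configuration: bad thresholds, degenerate simulation settings, unknown groups."""


class DataError(PlexquantError):
    """Invalid or inconsistent input data: missing columns, unknown proteins, empty groups."""
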