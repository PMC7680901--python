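"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class SigrevError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SigrevError):
    """Invalid configuration: bad thresholds, impossible fractions, missing paths."""


class DataError(SigrevError):
    """Structurally invalid or degenerate input data."""
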