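"""Exception hierarchy shared across the pipeline.

``ConfigError`` covers invalid user input (bad presets, impossible plans,
malformed specs) and maps to CLI exit code 2; ``DataError`` covers problems
with data on disk or inconsistent arrays and maps to exit code 3.
"""


class LsmosaicError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class ConfigError(LsmosaicError):
    """Invalid configuration, parameters or acquisition plan."""

    exit_code = 2


class PlanningError(ConfigError):
    """A mosaic plan cannot cover the requested volume."""


class DataError(LsmosaicError):
    """Inconsistent, missing or unreadable data."""

    exit_code = 3
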