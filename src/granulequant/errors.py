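"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, InputError -> 3,
anything else -> 4.
"""


class GranuleQuantError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(GranuleQuantError):
    """Invalid or inconsistent analysis configuration."""


class InputError(GranuleQuantError):
    """Missing, malformed or inconsistent input data."""


class PlacementError(GranuleQuantError):
    """Synthetic scene could not be placed without overlap."""
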