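"""Exception hierarchy shared by all stages.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class ChdsigError(Exception):
    """Base class for all package errors."""


class ConfigError(ChdsigError):
    """Invalid configuration or parameters."""


class DataError(ChdsigError):
    """Invalid or inconsistent input data."""
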