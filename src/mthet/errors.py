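"""Exception hierarchy.

ConfigError: bad configuration, references or annotation (exit code 2 at the CLI).
DataError: malformed or inconsistent input data (exit code 3 at the CLI).
"""


class MthetError(Exception):
    """Base class for all package errors."""


class ConfigError(MthetError):
    """Invalid configuration, reference or annotation."""


class DataError(MthetError):
    """Malformed or internally inconsistent input data."""
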