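"""Exception hierarchy.

``ConfigError`` signals a bad configuration or rule file (CLI exit code 1),
``DataError`` a problem with the input recordings or manifests (exit code 2).
"""


class AnsqError(Exception):
    """Base class for all package errors."""


class ConfigError(AnsqError):
    """Invalid configuration, rule file, or parameter combination."""


class DataError(AnsqError):
    """Invalid or inconsistent input data (recordings, manifests, tables)."""


class SignalQualityError(DataError):
    """Raw signal too degraded to process (e.g. undetectable R waves)."""


class ProtocolError(DataError):
    """Session events violate the autonomic-test protocol."""
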