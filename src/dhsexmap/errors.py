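class DhSexMapError(Exception):
    """Base class for package errors."""


class ConfigError(DhSexMapError):
    """Invalid configuration; the message names the offending field."""


class InputError(DhSexMapError):
    """Invalid or inconsistent input data."""
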