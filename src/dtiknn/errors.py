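"""Exception hierarchy shared across the package."""


class DtiknnError(Exception):
    """Base class for all package errors."""


class InputError(DtiknnError):
    """A user-supplied file or table violates its contract (CLI exit code 2)."""


class ParseError(InputError):
    """A file could not be parsed into the expected record structure."""


class ConfigError(DtiknnError):
    """A configuration value is out of its admissible range (CLI exit code 3)."""
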