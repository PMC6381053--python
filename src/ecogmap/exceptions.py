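"""Exception hierarchy shared across the package."""


class EcogMapError(Exception):
    """Base class for all package errors."""


class ConfigError(EcogMapError):
    """A configuration value violates an invariant. Names the offending field."""


class ProtocolError(EcogMapError):
    """Malformed or unknown wire data (e.g. an unknown descriptor byte)."""


class IncompletePacketError(EcogMapError):
    """The byte buffer ends mid-packet; the caller may await more bytes."""


class SchemaError(EcogMapError):
    """A serialized record fails structural validation on read."""


class DegenerateInputError(EcogMapError):
    """Numerically degenerate input (e.g. a constant window fed to the AR fit)."""
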