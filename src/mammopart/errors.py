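"""Exception hierarchy shared by all modules."""


class MammopartError(Exception):
    """Base class for all package errors."""


class FormatError(MammopartError):
    """A file is not in a supported or well-formed format."""


class ValidationError(MammopartError):
    """Data violates a documented invariant (duplicate ids, bad boxes, ...)."""


class ConfigError(MammopartError):
    """A configuration value is out of its valid range or inconsistent."""
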