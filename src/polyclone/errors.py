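"""Exception hierarchy shared across the package."""


class PolycloneError(Exception):
    """Base class for all package errors."""


class FormatError(PolycloneError):
    """A file does not conform to the documented dialect."""


class ValidationError(PolycloneError, ValueError):
    """A value violates a domain invariant."""


class ConfigError(PolycloneError, ValueError):
    """A configuration value is out of its legal range or unknown."""


class MissingEvidenceError(PolycloneError):
    """Read-level evidence required but absent.

    Raised by the subclonal caller when a site carries alternate-allele
    counts but no per-read records; such sites can only be handled by
    the count-based primary caller.
    """
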