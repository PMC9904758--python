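"""Exception hierarchy shared by all modules."""


class HistoAtlasError(Exception):
    """Base class for all package errors."""


class FormatError(HistoAtlasError):
    """A file could not be read or does not conform to its format."""


class ValidationError(HistoAtlasError):
    """Inputs violate a documented precondition or invariant."""
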