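"""Exception hierarchy shared across editscan modules."""


class EditscanError(Exception):
    """Base class for all editscan errors."""


class FormatError(EditscanError):
    """A file does not conform to the documented format."""


class ValidationError(EditscanError):
    """Parsed data violates a documented invariant."""


class MpileupParseError(FormatError):
    """An mpileup base string could not be parsed; carries the offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset
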