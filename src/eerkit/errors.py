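"""Exception hierarchy for eerkit."""


class EerError(Exception):
    """Base class for all eerkit errors."""


class ValidationError(EerError):
    """A domain object violates one of its invariants."""


class CodecError(EerError):
    """RLE encoding/decoding failure (unsorted input, corrupt payload, ...)."""


class EerFormatError(EerError):
    """Malformed EER container or MRC file."""
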